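"""Jury evaluation: contingency metrics, cross-validation, label shuffling.

The metric set is the screening-oriented quartet

    TNR = TN / (TN + FP)                    (true negative rate)
    PPV = TP / (TP + FP)                    (positive predictive value)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    BA  = (TP/(TP+FN) + TN/(TN+FP)) / 2     (balanced accuracy)

computed from pooled out-of-fold predictions of a stratified k-fold
cross-validation (fold-averaged values are recorded alongside; pooled is
primary). A zero denominator never raises: the metric is reported as 0 and
flagged "degenerate", which keeps label-shuffle controls well-defined when
a model predicts a single class.

The y-randomization control permutes the labels (class counts preserved)
and re-runs the identical cross-validation; near-zero MCC on shuffled
labels is the evidence that the unshuffled models learned real signal.
AUC is computed per member model by the Mann-Whitney rank statistic on the
pooled out-of-fold scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .descriptors import MinMaxNormalizer
from .errors import InputError
from .jury_models import (
    DEFAULT_SEED,
    MODEL_NAMES,
    ClassifierSpec,
    JuryClassifier,
)

METRIC_NAMES = ("TNR", "PPV", "MCC", "BA")


@dataclass(frozen=True)
class ContingencyTable:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise InputError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def contingency(y_true, y_pred) -> ContingencyTable:
    """Count TP/TN/FP/FN for binary vectors (positive class = 1)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise InputError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise InputError("empty prediction vectors")
    if not (set(np.unique(yt)) <= {0, 1} and set(np.unique(yp)) <= {0, 1}):
        raise InputError("labels and predictions must be binary (0/1)")
    return ContingencyTable(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def tnr(t: ContingencyTable) -> float:
    return _ratio(t.TN, t.TN + t.FP)


def ppv(t: ContingencyTable) -> float:
    return _ratio(t.TP, t.TP + t.FP)


def mcc(t: ContingencyTable) -> float:
    den = math.sqrt((t.TP + t.FP) * (t.TP + t.FN) * (t.TN + t.FP) * (t.TN + t.FN))
    return _ratio(t.TP * t.TN - t.FP * t.FN, den)


def ba(t: ContingencyTable) -> float:
    return 0.5 * (_ratio(t.TP, t.TP + t.FN) + _ratio(t.TN, t.TN + t.FP))


def degenerate_metrics(t: ContingencyTable) -> list[str]:
    """Names of metrics whose denominator vanishes for this table."""
    flags = []
    if t.TN + t.FP == 0:
        flags.append("TNR")
    if t.TP + t.FP == 0:
        flags.append("PPV")
    if (t.TP + t.FP) * (t.TP + t.FN) * (t.TN + t.FP) * (t.TN + t.FN) == 0:
        flags.append("MCC")
    if t.TP + t.FN == 0 or t.TN + t.FP == 0:
        flags.append("BA")
    return flags


def compute_metrics(t: ContingencyTable) -> dict:
    return {
        "TNR": tnr(t),
        "PPV": ppv(t),
        "MCC": mcc(t),
        "BA": ba(t),
        "degenerate": degenerate_metrics(t),
    }


def auc_mann_whitney(y_true, scores) -> float:
    """ROC AUC via the rank-sum statistic: P(score_pos > score_neg) + 0.5 ties.

    Returns 0.5 when either class is absent (uninformative by convention).
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(s)
    rank_sum_pos = float(ranks[yt == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass
class MetricsReport:
    """Cross-validation outcome for the three members and the consensus."""

    task: str
    seed: int
    k: int
    shuffled: bool
    pooled: dict[str, dict]                 # model -> metrics (+ auc for members)
    averaged: dict[str, dict[str, float]]   # model -> fold-mean metrics
    fold_tables: list[dict[str, dict]]      # per fold: model -> TP/TN/FP/FN
    fold_assignments: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "task": self.task,
                "seed": self.seed,
                "k": self.k,
                "shuffled": self.shuffled,
                "pooled": self.pooled,
                "averaged": self.averaged,
                "fold_tables": self.fold_tables,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, metrics in self.pooled.items():
            row = {"model": model}
            row.update({k: v for k, v in metrics.items() if k != "degenerate"})
            rows.append(row)
        return pd.DataFrame(rows)


def _check_cv_inputs(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("cross-validation needs both classes present")
    if counts.min() < k:
        raise InputError(
            f"class with {counts.min()} members cannot be split into {k} folds; "
            f"use k <= {counts.min()}"
        )


def cross_validate(
    X: pd.DataFrame,
    y,
    task: str = "5lo",
    specs: list[ClassifierSpec] | None = None,
    k: int = 10,
    seed: int = DEFAULT_SEED,
    shuffled: bool = False,
) -> MetricsReport:
    """Stratified k-fold CV of the jury on a raw (unnormalized) matrix.

    Per fold, the min-max normalizer and the three members are fit on the
    training 9/10 only, then votes and scores are collected on the held-out
    1/10; metrics are computed on the pooled out-of-fold predictions for
    each member and for the unanimity consensus.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    if len(X) != len(y):
        raise InputError(f"matrix has {len(X)} rows but {len(y)} labels")
    _check_cv_inputs(y, k)

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_votes = {name: np.zeros(len(y), dtype=int) for name in MODEL_NAMES}
    oof_scores = {name: np.zeros(len(y), dtype=float) for name in MODEL_NAMES}
    fold_of = np.full(len(y), -1, dtype=int)
    fold_tables: list[dict[str, dict]] = []
    fold_metrics: list[dict[str, dict]] = []

    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        normalizer = MinMaxNormalizer().fit(X.iloc[train_idx])
        X_train = normalizer.transform(X.iloc[train_idx])
        X_test = normalizer.transform(X.iloc[test_idx])
        jury = JuryClassifier(task=task, seed=seed, specs=specs)
        jury.fit(X_train, y[train_idx])
        votes = jury.predict_votes(X_test)
        scores = jury.predict_scores(X_test)
        fold_of[test_idx] = fold

        fold_table: dict[str, dict] = {}
        fold_metric: dict[str, dict] = {}
        fold_preds = {}
        for name in MODEL_NAMES:
            oof_votes[name][test_idx] = votes[name].to_numpy()
            oof_scores[name][test_idx] = scores[name].to_numpy()
            fold_preds[name] = votes[name].to_numpy()
        fold_preds["consensus"] = (votes.sum(axis=1).to_numpy() == 3).astype(int)
        for name, preds in fold_preds.items():
            t = contingency(y[test_idx], preds)
            fold_table[name] = {"TP": t.TP, "TN": t.TN, "FP": t.FP, "FN": t.FN}
            fold_metric[name] = compute_metrics(t)
        fold_tables.append(fold_table)
        fold_metrics.append(fold_metric)

    consensus_votes = (sum(oof_votes[name] for name in MODEL_NAMES) == 3).astype(int)

    pooled: dict[str, dict] = {}
    for name in MODEL_NAMES:
        t = contingency(y, oof_votes[name])
        pooled[name] = compute_metrics(t)
        pooled[name]["AUC"] = auc_mann_whitney(y, oof_scores[name])
    pooled["consensus"] = compute_metrics(contingency(y, consensus_votes))

    averaged = {
        name: {
            m: float(np.mean([fm[name][m] for fm in fold_metrics]))
            for m in METRIC_NAMES
        }
        for name in [*MODEL_NAMES, "consensus"]
    }

    return MetricsReport(
        task=task,
        seed=seed,
        k=k,
        shuffled=shuffled,
        pooled=pooled,
        averaged=averaged,
        fold_tables=fold_tables,
        fold_assignments=fold_of.tolist(),
    )


def shuffle_labels(y, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Uniform random permutation of the label vector (class counts kept)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
    y = np.asarray(y)
    return y[rng.permutation(len(y))]


def shuffle_label_control(
    X: pd.DataFrame,
    y,
    task: str = "5lo",
    specs: list[ClassifierSpec] | None = None,
    k: int = 10,
    seed: int = DEFAULT_SEED,
) -> MetricsReport:
    """The y-randomization control: shuffle labels, rerun the identical CV."""
    return cross_validate(
        X, shuffle_labels(y, seed), task=task, specs=specs, k=k, seed=seed, shuffled=True
    )
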