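"""The three-classifier jury and its member models.

The screening model is a jury of three heterogeneous classifiers —
gradient-boosted trees, logistic regression and naive Bayes — trained on
normalized physicochemical descriptors. Each member casts a binary vote
(positive-class score >= 0.5); a molecule's *tier* is the number of
positive votes, and only unanimous (tier-3, "triple-positive") molecules
are treated as consensus positives. Because unanimity is an intersection
of the members' positive sets, the consensus can only shed false
positives: its true-negative rate dominates every member's.

Member defaults mirror a screening configuration tuned for a roughly
balanced ~2.5k-molecule training set (the "5lo" task): GBT with tree
depth 4, 500 trees, learning rate 0.05; logistic regression trained by
batch gradient descent capped at 100 epochs with step size 0.1 and loss
tolerance 1e-5; Gaussian naive Bayes. The "flap" task variant (a heavily
positive-skewed set) raises the GBT learning rate to 0.15 and floors each
naive-Bayes class-conditional density at 0.005. The shared random state
defaults to 1234.

Logistic regression is deliberately trained by gradient descent rather
than a closed-form/second-order solver so that the epoch cap, step size
and convergence epsilon are real knobs, and naive Bayes is a thin
extension of sklearn's GaussianNB adding the density floor (floor 0
reduces exactly to GaussianNB).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.utils.validation import check_is_fitted, check_X_y

from .chem import mol_from_smiles
from .descriptors import DescriptorCalculator, MinMaxNormalizer
from .errors import ConfigurationError, InputError, TrainingError

MODEL_NAMES = ("gbt", "logreg", "nbayes")
DEFAULT_SEED = 1234
VOTE_THRESHOLD = 0.5
CONSENSUS_TIER = 3

#: task presets: hyperparameters per member model
TASK_PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "5lo": {
        "gbt": {"tree_depth": 4, "n_trees": 500, "learning_rate": 0.05},
        "logreg": {"max_epochs": 100, "epsilon": 1e-5, "step_size": 0.1},
        "nbayes": {"probability_floor": 0.0},
    },
    "flap": {
        "gbt": {"tree_depth": 4, "n_trees": 500, "learning_rate": 0.15},
        "logreg": {"max_epochs": 100, "epsilon": 1e-5, "step_size": 0.1},
        "nbayes": {"probability_floor": 0.005},
    },
}


class GradientDescentLogisticRegression(ClassifierMixin, BaseEstimator):
    """Binary logistic regression fit by full-batch gradient descent.

    Minimizes the mean log-loss of ``sigmoid(Xw + b)`` with a constant
    learning rate (``step_size``), stopping after ``max_epochs`` epochs or
    when the absolute change in loss between epochs falls below
    ``epsilon``. No regularization. Inputs are expected pre-scaled
    (here: min-max normalized descriptors).
    """

    def __init__(self, max_epochs: int = 100, step_size: float = 0.1, epsilon: float = 1e-5):
        self.max_epochs = max_epochs
        self.step_size = step_size
        self.epsilon = epsilon

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise TrainingError("logistic regression needs exactly two classes")
        t = (y == self.classes_[1]).astype(float)
        n, d = X.shape
        w = np.zeros(d)
        b = 0.0
        prev_loss = np.inf
        for epoch in range(self.max_epochs):
            p = 1.0 / (1.0 + np.exp(-(X @ w + b)))
            grad_w = X.T @ (p - t) / n
            grad_b = float(np.mean(p - t))
            w -= self.step_size * grad_w
            b -= self.step_size * grad_b
            eps = 1e-12
            loss = -float(np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))
            if abs(prev_loss - loss) < self.epsilon:
                break
            prev_loss = loss
        self.coef_ = w.reshape(1, -1)
        self.intercept_ = np.array([b])
        self.n_iter_ = epoch + 1
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.ravel() + self.intercept_[0]

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


class FlooredGaussianNB(GaussianNB):
    """Gaussian naive Bayes with a floor on each class-conditional density.

    ``probability_floor`` bounds every per-feature class-conditional
    density value from below before the log-likelihoods are summed,
    preventing a single extreme feature from vetoing a class. A floor of
    0 is exactly sklearn's GaussianNB.
    """

    def __init__(self, probability_floor: float = 0.0, var_smoothing: float = 1e-9):
        super().__init__(var_smoothing=var_smoothing)
        self.probability_floor = probability_floor

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        if self.probability_floor <= 0:
            return super()._joint_log_likelihood(X)
        floor_log = np.log(self.probability_floor)
        jll = []
        for i in range(len(self.classes_)):
            var = self.var_[i]
            log_dens = -0.5 * np.log(2.0 * np.pi * var) - 0.5 * (X - self.theta_[i]) ** 2 / var
            log_dens = np.maximum(log_dens, floor_log)
            jll.append(np.log(self.class_prior_[i]) + log_dens.sum(axis=1))
        return np.array(jll).T


@dataclass(frozen=True)
class ClassifierSpec:
    """One jury member: model kind, hyperparameters and random state."""

    kind: str
    hyperparameters: dict[str, float] = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def build(self) -> BaseEstimator:
        hp = self.hyperparameters
        if self.kind == "gbt":
            return GradientBoostingClassifier(
                max_depth=int(hp.get("tree_depth", 4)),
                n_estimators=int(hp.get("n_trees", 500)),
                learning_rate=float(hp.get("learning_rate", 0.05)),
                random_state=self.seed,
            )
        if self.kind == "logreg":
            return GradientDescentLogisticRegression(
                max_epochs=int(hp.get("max_epochs", 100)),
                step_size=float(hp.get("step_size", 0.1)),
                epsilon=float(hp.get("epsilon", 1e-5)),
            )
        if self.kind == "nbayes":
            return FlooredGaussianNB(
                probability_floor=float(hp.get("probability_floor", 0.0))
            )
        raise ConfigurationError(f"unknown classifier kind: {self.kind!r}")


def default_specs(task: str = "5lo", seed: int = DEFAULT_SEED) -> list[ClassifierSpec]:
    """The three member specs for a task preset ('5lo' or 'flap')."""
    if task not in TASK_PRESETS:
        raise ConfigurationError(f"unknown task {task!r}; expected one of {sorted(TASK_PRESETS)}")
    preset = TASK_PRESETS[task]
    return [ClassifierSpec(kind=k, hyperparameters=dict(preset[k]), seed=seed) for k in MODEL_NAMES]


def train_classifier(spec: ClassifierSpec, X, y, seed: int | None = None) -> BaseEstimator:
    """Fit one member model; deterministic given (spec, data, seed)."""
    if seed is not None and seed != spec.seed:
        spec = ClassifierSpec(spec.kind, dict(spec.hyperparameters), seed)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    model = spec.build()
    return model.fit(np.asarray(X, dtype=float), y)


@dataclass
class VoteRecord:
    """Per-molecule jury outcome: member votes and the resulting tier."""

    molecule_id: str
    votes: dict[str, int]
    tier: int

    @property
    def consensus_positive(self) -> bool:
        return self.tier == CONSENSUS_TIER


def jury_vote(per_model_votes, molecule_id: str = "") -> VoteRecord:
    """Combine exactly three binary votes into a tier (the vote sum)."""
    if isinstance(per_model_votes, dict):
        names, votes = list(per_model_votes), list(per_model_votes.values())
    else:
        votes = list(per_model_votes)
        names = list(MODEL_NAMES)
    if len(votes) != 3:
        raise InputError(f"expected exactly 3 votes, got {len(votes)}")
    if any(v not in (0, 1) for v in votes):
        raise InputError(f"votes must be binary, got {votes}")
    return VoteRecord(molecule_id=molecule_id, votes=dict(zip(names, votes)), tier=int(sum(votes)))


class JuryClassifier(ClassifierMixin, BaseEstimator):
    """Unanimity-consensus jury over the three member classifiers.

    ``fit``/``predict`` follow sklearn conventions; ``predict`` returns the
    consensus label (1 iff all three members vote positive). Per-member
    votes, scores and tiers are exposed separately for the tiered
    screening reports.

    Parameters
    ----------
    task : {'5lo', 'flap'}
        Hyperparameter preset for the three members.
    seed : int
        Shared random state (only the GBT member consumes randomness).
    specs : list of ClassifierSpec, optional
        Explicit member specs; overrides ``task``.
    vote_threshold : float
        Positive-class score cutoff for a member vote.
    """

    def __init__(
        self,
        task: str = "5lo",
        seed: int = DEFAULT_SEED,
        specs: list[ClassifierSpec] | None = None,
        vote_threshold: float = VOTE_THRESHOLD,
    ):
        self.task = task
        self.seed = seed
        self.specs = specs
        self.vote_threshold = vote_threshold

    def _member_specs(self) -> list[ClassifierSpec]:
        if self.specs is not None:
            if len(self.specs) != 3:
                raise ConfigurationError("a jury takes exactly three member specs")
            return list(self.specs)
        return default_specs(self.task, self.seed)

    def fit(self, X, y):
        X_arr, y_arr = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
        self.classes_ = np.unique(y_arr)
        if len(self.classes_) < 2:
            raise TrainingError("training labels contain a single class")
        self.specs_ = self._member_specs()
        self.models_ = {
            spec.kind: train_classifier(spec, X_arr, y_arr) for spec in self.specs_
        }
        return self

    def predict_scores(self, X) -> pd.DataFrame:
        """Per-member positive-class scores in [0, 1]."""
        check_is_fitted(self, "models_")
        X_arr = np.asarray(X, dtype=float)
        index = X.index if isinstance(X, pd.DataFrame) else None
        scores = {
            name: model.predict_proba(X_arr)[:, list(model.classes_).index(1)]
            for name, model in self.models_.items()
        }
        return pd.DataFrame(scores, index=index)[list(MODEL_NAMES)]

    def predict_votes(self, X) -> pd.DataFrame:
        return (self.predict_scores(X) >= self.vote_threshold).astype(int)

    def predict_tier(self, X) -> pd.Series:
        tiers = self.predict_votes(X).sum(axis=1)
        tiers.name = "tier"
        return tiers

    def predict(self, X):
        return (self.predict_tier(X).to_numpy() == CONSENSUS_TIER).astype(int)


@dataclass
class JuryModel:
    """A deployable screening model: featurizer + normalizer + fitted jury.

    Ties the jury to the descriptor panel it was trained on
    (``panel_version``); screening a library recomputes and normalizes the
    same panel before voting.
    """

    calculator: DescriptorCalculator
    normalizer: MinMaxNormalizer
    jury: JuryClassifier
    training_id: str = ""

    @property
    def panel_version(self) -> str:
        return self.calculator.panel_version_

    def featurize(self, smiles_list) -> pd.DataFrame:
        return self.normalizer.transform(self.calculator.transform(smiles_list))

    def save(self, path: str | Path) -> None:
        """Persist to a zip archive: JSON manifest + joblib payload."""
        manifest = {
            "panel_version": self.panel_version,
            "training_id": self.training_id,
            "seed": self.jury.seed,
            "task": self.jury.task,
            "specs": [
                {"kind": s.kind, "hyperparameters": s.hyperparameters, "seed": s.seed}
                for s in self.jury.specs_
            ],
            "normalization": self.normalizer.to_dict(),
        }
        buf = io.BytesIO()
        joblib.dump(self, buf)
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            # fixed entry timestamps keep reruns byte-identical
            for name, payload in (
                ("manifest.json", json.dumps(manifest, indent=2).encode()),
                ("model.joblib", buf.getvalue()),
            ):
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, payload)

    @classmethod
    def load(cls, path: str | Path) -> "JuryModel":
        with zipfile.ZipFile(path) as zf:
            with zf.open("model.joblib") as fh:
                return joblib.load(io.BytesIO(fh.read()))

    @staticmethod
    def read_manifest(path: str | Path) -> dict:
        with zipfile.ZipFile(path) as zf:
            return json.loads(zf.read("manifest.json"))


def fit_jury_model(
    training_smiles,
    y,
    task: str = "5lo",
    seed: int = DEFAULT_SEED,
    panel=None,
    specs: list[ClassifierSpec] | None = None,
    training_id: str = "",
) -> JuryModel:
    """Featurize a curated training set and fit the full screening model."""
    calculator = DescriptorCalculator(panel=panel).fit(training_smiles)
    matrix = calculator.transform(training_smiles)
    y_series = pd.Series(np.asarray(y), index=list(training_smiles)).loc[matrix.index]
    normalizer = MinMaxNormalizer().fit(matrix)
    jury = JuryClassifier(task=task, seed=seed, specs=specs)
    jury.fit(normalizer.transform(matrix), y_series.to_numpy())
    return JuryModel(calculator=calculator, normalizer=normalizer, jury=jury, training_id=training_id)


def screen_library(model: JuryModel, candidate_smiles) -> tuple[pd.DataFrame, dict[int, int], list[str]]:
    """Vote every candidate; returns (per-candidate report, tier counts, failures).

    Candidates whose descriptors cannot be computed are excluded from the
    report and listed in ``failures``; screening never aborts on a single
    bad molecule.
    """
    candidates = list(candidate_smiles)
    if not candidates:
        empty = pd.DataFrame(columns=[*MODEL_NAMES, "tier"])
        return empty, {t: 0 for t in range(4)}, []
    failures: list[str] = []
    parseable: list[str] = []
    for smi in candidates:
        try:
            mol_from_smiles(smi)
            parseable.append(smi)
        except InputError:
            failures.append(smi)
    matrix = model.featurize(parseable)
    failures.extend(model.calculator.dropped_)
    votes = model.jury.predict_votes(matrix)
    report = votes.copy()
    report["tier"] = votes.sum(axis=1)
    tier_counts = {t: int((report["tier"] == t).sum()) for t in range(4)}
    return report, tier_counts, failures
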