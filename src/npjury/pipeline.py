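"""End-to-end orchestration: curate -> featurize -> evaluate -> train ->
screen -> fragments -> similarity, as one configured, reproducible run.

Every run writes its stage outputs into one directory together with a
``manifest.json`` capturing the config snapshot, input checksums, the
resolved descriptor panel version, seeds, per-stage record counts and the
package version — enough to re-execute the run byte-identically. A stage
failure stops the run at that stage (prior outputs are left intact) and
is re-raised with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .curation import curate, read_activity_table
from .descriptors import DEFAULT_PANEL, DescriptorCalculator
from .errors import ConfigurationError, NpjuryError
from .evaluation import cross_validate, shuffle_label_control
from .fragments import enrichment, fragment_frequencies
from .jury_models import ClassifierSpec, MODEL_NAMES, TASK_PRESETS, fit_jury_model, screen_library
from .similarity import nearest_known
from .synthetic_data import GeneratorConfig, generate_benchmark

_TASKS = ("5lo", "flap", "custom")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``activity_table=None`` a synthetic benchmark of ``n_synthetic``
    molecules is drawn (the truth JSON lands next to the stage outputs), so
    the pipeline is exercisable end-to-end without external data.
    """

    outdir: str | Path
    task: str = "5lo"
    seed: int = 1234
    threshold_nM: float = 1000.0
    k: int = 10
    activity_table: str | Path | None = None
    candidate_library: str | Path | None = None
    annotations: str | Path | None = None
    panel: tuple[str, ...] | None = None
    n_synthetic: int = 2000
    noise_sd: float = 0.5
    run_shuffle_control: bool = True
    hyperparameter_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in _TASKS:
            raise ConfigurationError(f"unknown task {self.task!r}; expected one of {_TASKS}")
        if self.task == "custom" and not self.hyperparameter_overrides:
            raise ConfigurationError("task 'custom' needs hyperparameter_overrides")

    def member_specs(self) -> list[ClassifierSpec]:
        base_task = self.task if self.task in TASK_PRESETS else "5lo"
        merged = {k: dict(v) for k, v in TASK_PRESETS[base_task].items()}
        for kind, overrides in self.hyperparameter_overrides.items():
            if kind not in merged:
                raise ConfigurationError(f"unknown model kind in overrides: {kind!r}")
            merged[kind].update(overrides)
        return [
            ClassifierSpec(kind=k, hyperparameters=merged[k], seed=self.seed)
            for k in MODEL_NAMES
        ]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for name in ("activity_table", "candidate_library", "annotations"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise ConfigurationError(f"{name} does not exist: {value}")

    snapshot = dataclasses.asdict(config)
    snapshot["outdir"] = str(outdir)
    for key in ("activity_table", "candidate_library", "annotations"):
        if snapshot[key] is not None:
            snapshot[key] = str(snapshot[key])
    manifest: dict = {
        "version": __version__,
        "config": snapshot,
        "seed": config.seed,
        "specs": [
            {"kind": s.kind, "hyperparameters": s.hyperparameters, "seed": s.seed}
            for s in config.member_specs()
        ],
        "inputs": {},
        "counts": {},
    }
    stage = "setup"
    try:
        # --- input stage: load or simulate the activity table -------------
        stage = "input"
        if config.activity_table is not None:
            table_path = Path(config.activity_table)
            manifest["inputs"]["activity_table"] = _sha256(table_path)
            records = read_activity_table(table_path)
        else:
            benchmark = generate_benchmark(
                GeneratorConfig(
                    n_molecules=config.n_synthetic,
                    seed=config.seed,
                    noise_sd=config.noise_sd,
                )
            )
            table_path, truth_path = benchmark.write(outdir / "synthetic")
            manifest["inputs"]["activity_table"] = _sha256(table_path)
            manifest["inputs"]["truth"] = _sha256(truth_path)
            records = benchmark.records
        manifest["counts"]["raw_records"] = len(records)

        # --- curation -----------------------------------------------------
        stage = "curate"
        dataset = curate(records, threshold_nM=config.threshold_nM)
        dataset.write(outdir / "curated.csv")
        dataset.write_provenance(outdir / "provenance.json")
        manifest["counts"]["curated_molecules"] = len(dataset.entries)
        manifest["counts"]["strong_modulators"] = int(dataset.entries["label"].sum())

        # --- featurization ------------------------------------------------
        stage = "featurize"
        calculator = DescriptorCalculator(panel=config.panel).fit(dataset.smiles)
        matrix = calculator.transform(dataset.smiles)
        manifest["panel_version"] = calculator.panel_version_
        manifest["counts"]["featurized_molecules"] = len(matrix)
        labels = dataset.labels.loc[matrix.index]
        matrix.to_csv(outdir / "descriptors.csv")

        # --- cross-validated evaluation + y-randomization control ---------
        stage = "evaluate"
        specs = config.member_specs()
        report = cross_validate(matrix, labels, task=config.task, specs=specs,
                                k=config.k, seed=config.seed)
        report.to_json(outdir / "metrics.json")
        manifest["metrics"] = {m: report.pooled[m] for m in report.pooled}
        if config.run_shuffle_control:
            shuffled = shuffle_label_control(matrix, labels, task=config.task,
                                             specs=specs, k=config.k, seed=config.seed)
            shuffled.to_json(outdir / "metrics_shuffled.json")
            manifest["metrics_shuffled"] = {m: shuffled.pooled[m] for m in shuffled.pooled}

        # --- final model on the full curated set --------------------------
        stage = "train"
        model = fit_jury_model(
            matrix.index.tolist(), labels.to_numpy(), task=config.task,
            seed=config.seed, panel=config.panel, specs=specs,
            training_id=manifest["inputs"]["activity_table"][:12],
        )
        model.save(outdir / "model.npjury.zip")

        # --- candidate screening ------------------------------------------
        stage = "screen"
        if config.candidate_library is not None:
            candidates = read_smiles_file(config.candidate_library)
            manifest["inputs"]["candidate_library"] = _sha256(Path(config.candidate_library))
            screen_report, tier_counts, failures = screen_library(model, list(candidates["smiles"]))
            screen_report = screen_report.reset_index(names="smiles")
            if config.annotations is not None:
                ann = pd.read_csv(config.annotations)
                screen_report = screen_report.merge(ann, on="smiles", how="left")
            screen_report.to_csv(outdir / "screen.csv", index=False)
            manifest["counts"]["screened"] = int(len(screen_report))
            manifest["counts"]["screen_failures"] = len(failures)
            manifest["tier_counts"] = {str(t): n for t, n in tier_counts.items()}

        # --- fragment enrichment ------------------------------------------
        stage = "fragments"
        strong = dataset.entries[dataset.entries["label"] == 1]["canonical_smiles"]
        weak = dataset.entries[dataset.entries["label"] == 0]["canonical_smiles"]
        if len(strong) and len(weak):
            rep = enrichment(fragment_frequencies(strong), fragment_frequencies(weak))
            rep.ranked.to_csv(outdir / "fragment_enrichment.csv", index=False)
            manifest["counts"]["shared_fragments"] = int(len(rep.ranked))
            manifest["counts"]["strong_only_fragments"] = len(rep.strong_only)
            manifest["counts"]["weak_only_fragments"] = len(rep.weak_only)

        # --- novelty of consensus hits vs known strong modulators ---------
        stage = "similarity"
        if config.candidate_library is not None and manifest["tier_counts"].get("3", 0):
            hits = screen_report.loc[screen_report["tier"] == 3, "smiles"]
            sim = nearest_known(hits, list(strong))
            sim.to_csv(outdir / "similarity.csv", index=False)
            manifest["counts"]["novelty_assessed"] = int(len(hits))
    except NpjuryError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_smiles_file(path: str | Path) -> pd.DataFrame:
    """One SMILES per line, optional whitespace-separated name column."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        rows.append({"smiles": parts[0], "name": parts[1] if len(parts) > 1 else f"mol{i}"})
    return pd.DataFrame(rows, columns=["smiles", "name"])
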