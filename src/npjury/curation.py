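"""Bioactivity-table curation: filter, deduplicate, binarize.

The curation policy mirrors how public bioactivity exports are trimmed to a
modelling set: keep only exact (relation '=') IC50/Kd/Ki measurements
reported in nM with a positive value and a parseable structure, collapse
replicate measurements of one molecule (canonical SMILES of the largest
organic fragment) to their median, and call a molecule a strong modulator
(label 1) when its aggregated potency is strictly below the threshold
(default 1000 nM, i.e. 1 uM).

No unit conversion is performed: a value reported in uM is dropped, not
rescaled, so curated record counts are an auditable function of the raw
table. Drop reasons are itemized by the first failing criterion in the
fixed order type, relation, units, value, smiles.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import canonical_smiles
from .errors import EmptyDatasetError, FormatError, InputError

REQUIRED_COLUMNS = (
    "molecule_id",
    "smiles",
    "standard_type",
    "standard_relation",
    "standard_value",
    "standard_units",
)

KEPT_TYPES = frozenset({"ic50", "kd", "ki"})
#: drop reasons, checked in this order; a record is charged to the first
FILTER_ORDER = ("type", "relation", "units", "value", "smiles")
DEFAULT_THRESHOLD_NM = 1000.0


@dataclass
class ActivityRecord:
    """One raw activity measurement as exported from a bioactivity database."""

    molecule_id: str
    smiles: str
    standard_type: str
    standard_relation: str
    standard_value: float | None
    standard_units: str
    value_unparseable: bool = False


@dataclass
class CuratedDataset:
    """Deduplicated, binarized modelling set plus filtering provenance."""

    entries: pd.DataFrame  # canonical_smiles, value_nM, label, n_replicates
    provenance: dict[str, int] = field(default_factory=dict)
    threshold_nM: float = DEFAULT_THRESHOLD_NM

    @property
    def smiles(self) -> list[str]:
        return self.entries["canonical_smiles"].tolist()

    @property
    def labels(self) -> pd.Series:
        return self.entries.set_index("canonical_smiles")["label"]

    def write(self, path: str | Path) -> None:
        self.entries.to_csv(path, index=False)

    def write_provenance(self, path: str | Path) -> None:
        payload = {"threshold_nM": self.threshold_nM, "dropped": self.provenance}
        Path(path).write_text(json.dumps(payload, indent=2))


def _sniff_delimiter(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path, newline="") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a ChEMBL-export-like CSV/TSV into activity records.

    Rows whose standard_value does not parse as a number are retained with
    the value absent and flagged, so that filtering can account for them.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"activity table not found: {path}")
    frame = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"activity table {path} is missing columns: {missing}")

    records: list[ActivityRecord] = []
    for row in frame.itertuples(index=False):
        raw = getattr(row, "standard_value").strip()
        try:
            value: float | None = float(raw)
            unparseable = False
        except ValueError:
            value, unparseable = None, True
        records.append(
            ActivityRecord(
                molecule_id=getattr(row, "molecule_id"),
                smiles=getattr(row, "smiles"),
                standard_type=getattr(row, "standard_type"),
                standard_relation=getattr(row, "standard_relation"),
                standard_value=value,
                standard_units=getattr(row, "standard_units"),
                value_unparseable=unparseable,
            )
        )
    return records


def write_activity_table(records: list[ActivityRecord], path: str | Path) -> None:
    rows = [
        {
            "molecule_id": r.molecule_id,
            "smiles": r.smiles,
            "standard_type": r.standard_type,
            "standard_relation": r.standard_relation,
            "standard_value": "" if r.standard_value is None else r.standard_value,
            "standard_units": r.standard_units,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def _first_failure(record: ActivityRecord) -> str | None:
    if record.standard_type.strip().lower() not in KEPT_TYPES:
        return "type"
    if record.standard_relation.strip() != "=":
        return "relation"
    if record.standard_units.strip().lower() != "nm":
        return "units"
    if record.value_unparseable:
        return "unparseable_value"
    if record.standard_value is None or record.standard_value <= 0:
        return "value"
    try:
        canonical_smiles(record.smiles, context=record.molecule_id)
    except InputError:
        return "smiles"
    return None


def filter_records(
    records: list[ActivityRecord],
) -> tuple[list[ActivityRecord], dict[str, int]]:
    """Keep exact IC50/Kd/Ki measurements in nM; itemize drops by reason."""
    kept: list[ActivityRecord] = []
    drops = {k: 0 for k in FILTER_ORDER}
    drops["unparseable_value"] = 0
    for record in records:
        reason = _first_failure(record)
        if reason is None:
            kept.append(record)
        else:
            drops[reason] += 1
    return kept, {k: v for k, v in drops.items() if v}


def deduplicate(records: list[ActivityRecord]) -> pd.DataFrame:
    """Group filtered records by canonical SMILES; aggregate values by median.

    Returns a frame (canonical_smiles, value_nM, n_replicates); the median
    is the replicate-aggregation policy — robust to one discordant replicate
    and deterministic.
    """
    rows = [
        (canonical_smiles(r.smiles, context=r.molecule_id), r.standard_value)
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=["canonical_smiles", "value_nM"])
    grouped = (
        frame.groupby("canonical_smiles", sort=True)["value_nM"]
        .agg(value_nM="median", n_replicates="size")
        .reset_index()
    )
    return grouped


def binarize(value_nM: float, threshold_nM: float = DEFAULT_THRESHOLD_NM) -> int:
    """1 (strong modulator) iff 0 < value < threshold; the boundary is weak."""
    if value_nM is None or value_nM <= 0:
        raise InputError(f"potency must be positive, got {value_nM!r}")
    return int(value_nM < threshold_nM)


def curate(
    records: list[ActivityRecord], threshold_nM: float = DEFAULT_THRESHOLD_NM
) -> CuratedDataset:
    """Filter, deduplicate and binarize raw records into a modelling set."""
    kept, drops = filter_records(records)
    if not kept:
        raise EmptyDatasetError(
            f"no records survived filtering (dropped: {drops or 'nothing to drop'})"
        )
    entries = deduplicate(kept)
    entries["label"] = [binarize(v, threshold_nM) for v in entries["value_nM"]]
    entries = entries[["canonical_smiles", "value_nM", "label", "n_replicates"]]
    provenance = dict(drops)
    provenance["retained_records"] = len(kept)
    return CuratedDataset(entries=entries, provenance=provenance, threshold_nM=threshold_nM)


def read_curated(path: str | Path) -> CuratedDataset:
    """Load a curated dataset previously written with ``CuratedDataset.write``."""
    frame = pd.read_csv(path)
    needed = {"canonical_smiles", "value_nM", "label"}
    missing = needed - set(frame.columns)
    if missing:
        raise FormatError(f"curated dataset {path} is missing columns: {sorted(missing)}")
    if "n_replicates" not in frame.columns:
        frame["n_replicates"] = 1
    return CuratedDataset(entries=frame, provenance={}, threshold_nM=DEFAULT_THRESHOLD_NM)
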