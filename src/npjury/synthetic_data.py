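"""Synthetic bioactivity benchmarks with a planted, recoverable signal.

Every downstream stage (curation, featurization, jury training, evaluation,
fragment enrichment, similarity) is exercisable without external data via
this module. It emulates a public bioactivity export:

* a molecule library drawn from a small grammar — linear/branched alkyl
  chains and benzene / pyridine / furan / cyclohexane scaffolds decorated
  with hydroxyl, methoxy, halogen, carbonyl (acetyl), amine and carboxyl
  substituents — so every emitted SMILES is valid by construction;
* continuous potencies in nM derived from a latent variable
  ``z = w . d(mol) + eps`` over three named physicochemical descriptors
  (a lipophilicity, a polar-surface and a size term, standardized across
  the draw), with ``eps ~ Normal(0, noise_sd)``;
* the strong/weak label is 1 iff z exceeds the sample median (balanced
  classes by construction) and the emitted potency is
  ``1000 * exp(-(z - median) / sd(z))`` nM, so the label boundary sits
  exactly at the 1000 nM curation cutoff;
* curation decoys: a configurable fraction of records carry non-'='
  relations or non-nM units (their molecules are lost to strict curation,
  on purpose), and a fraction of library entries are replicate records
  with jittered values to exercise deduplication.

A single seed drives four independent derived streams (molecule identity,
latent noise, record decoration, duplicate selection), so changing e.g.
``duplicate_rate`` never perturbs which molecules are generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit.Chem import Crippen, Descriptors

from .chem import canonical_smiles, mol_from_smiles
from .curation import ActivityRecord, write_activity_table
from .errors import ConfigurationError, InputError

#: Latent-signal descriptors (lipophilicity, polar surface, size) and their
#: fixed weights on the standardized scale.
TRUTH_WEIGHTS: dict[str, float] = {"MolLogP": 1.0, "TPSA": -0.8, "MolWt": 0.5}

_TRUTH_FUNCS = {
    "MolLogP": Crippen.MolLogP,
    "TPSA": Descriptors.TPSA,
    "MolWt": Descriptors.MolWt,
}

_SUBSTITUENTS = (
    "(O)",        # hydroxyl
    "(OC)",       # methoxy
    "(F)",
    "(Cl)",
    "(Br)",
    "(C(C)=O)",   # carbonyl (acetyl)
    "(N)",        # amine
    "(C(=O)O)",   # carboxyl
)

# ring templates: slots are optional substituent branches
_RING_TEMPLATES = {
    "benzene": ("c1c{0}c{1}c{2}c{3}c1", 4),
    "pyridine": ("c1c{0}c{1}nc{2}c1", 3),
    "furan": ("c1c{0}c{1}oc1", 2),
    "cyclohexane": ("C1C{0}C{1}C{2}C{3}C1", 4),
}

_DEFAULT_SCAFFOLD_WEIGHTS = {
    "chain": 0.30,
    "benzene": 0.25,
    "cyclohexane": 0.15,
    "pyridine": 0.15,
    "furan": 0.15,
}

_N_SUB_PROBS = np.array([0.25, 0.35, 0.25, 0.15])  # 0..3 substituents


def _check_fractions(name: str, mix: dict[str, float]) -> None:
    if any(v < 0 for v in mix.values()):
        raise ConfigurationError(f"{name} fractions must be non-negative: {mix}")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} fractions must sum to 1: {mix}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of a synthetic benchmark draw."""

    n_molecules: int
    seed: int = 1234
    noise_sd: float = 0.5
    duplicate_rate: float = 0.1
    unit_mix: dict[str, float] = field(
        default_factory=lambda: {"nM": 0.85, "uM": 0.10, "other": 0.05}
    )
    relation_mix: dict[str, float] = field(
        default_factory=lambda: {"=": 0.85, ">": 0.10, "<": 0.05}
    )
    scaffold_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SCAFFOLD_WEIGHTS)
    )

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 <= self.duplicate_rate <= 1:
            raise ConfigurationError("duplicate_rate must be in [0, 1]")
        _check_fractions("unit_mix", self.unit_mix)
        _check_fractions("relation_mix", self.relation_mix)
        if set(self.unit_mix) != {"nM", "uM", "other"}:
            raise ConfigurationError("unit_mix keys must be {nM, uM, other}")
        if set(self.relation_mix) != {"=", ">", "<"}:
            raise ConfigurationError("relation_mix keys must be {=, >, <}")
        unknown = set(self.scaffold_weights) - set(_DEFAULT_SCAFFOLD_WEIGHTS)
        if unknown:
            raise ConfigurationError(f"unknown scaffolds: {sorted(unknown)}")
        if any(w < 0 for w in self.scaffold_weights.values()) or (
            sum(self.scaffold_weights.values()) <= 0
        ):
            raise ConfigurationError("scaffold_weights must be non-negative, sum > 0")


@dataclass
class SyntheticBenchmark:
    """A generated activity table plus the planted ground truth."""

    records: list[ActivityRecord]
    truth_labels: dict[str, int]
    truth_weights: dict[str, float]
    seed: int
    noise_sd: float

    def write(self, out_prefix: str | Path) -> tuple[Path, Path]:
        """Write the activity CSV and the truth JSON; returns both paths."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        table = out_prefix.with_suffix(".activity.csv")
        truth = out_prefix.with_suffix(".truth.json")
        write_activity_table(self.records, table)
        truth.write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "noise_sd": self.noise_sd,
                    "truth_weights": self.truth_weights,
                    "truth_labels": self.truth_labels,
                },
                indent=2,
            )
        )
        return table, truth


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _build_chain(rng: np.random.Generator) -> str:
    length = int(rng.integers(4, 13))
    n_subs = int(rng.choice(4, p=_N_SUB_PROBS))
    slots = [""] * length
    interior = list(range(1, length - 1))
    for pos in rng.choice(interior, size=min(n_subs, len(interior)), replace=False):
        # branched alkyl chains: a methyl branch or a grammar substituent
        slots[pos] = "(C)" if rng.random() < 0.4 else str(rng.choice(_SUBSTITUENTS))
    return "".join("C" + s for s in slots)


def _build_ring(rng: np.random.Generator, scaffold: str) -> str:
    template, n_slots = _RING_TEMPLATES[scaffold]
    n_subs = int(rng.choice(4, p=_N_SUB_PROBS))
    slots = [""] * n_slots
    for pos in rng.choice(n_slots, size=min(n_subs, n_slots), replace=False):
        slots[pos] = str(rng.choice(_SUBSTITUENTS))
    return template.format(*slots)


def generate_library(config: GeneratorConfig) -> list[str]:
    """Draw ``n_molecules`` valid SMILES from the scaffold grammar.

    A ``duplicate_rate`` fraction of entries are verbatim copies of earlier
    entries (replicate measurements for the curation stage to collapse).
    """
    mol_rng = _stream(config.seed, 0)
    dup_rng = _stream(config.seed, 3)
    n_dup = int(round(config.n_molecules * config.duplicate_rate))
    n_fresh = max(config.n_molecules - n_dup, 1)
    n_dup = config.n_molecules - n_fresh

    names = sorted(config.scaffold_weights)
    weights = np.array([config.scaffold_weights[n] for n in names], dtype=float)
    weights /= weights.sum()

    fresh: list[str] = []
    for _ in range(n_fresh):
        scaffold = str(mol_rng.choice(names, p=weights))
        smi = _build_chain(mol_rng) if scaffold == "chain" else _build_ring(mol_rng, scaffold)
        fresh.append(smi)

    library = list(fresh)
    for _ in range(n_dup):
        library.append(fresh[int(dup_rng.integers(len(fresh)))])
    return library


def _truth_descriptors(unique_smiles: list[str]) -> np.ndarray:
    cols = []
    for name in TRUTH_WEIGHTS:
        func = _TRUTH_FUNCS[name]
        cols.append([func(mol_from_smiles(s, context=s)) for s in unique_smiles])
    return np.array(cols, dtype=float).T  # molecules x descriptors


def plant_activity(
    smiles_list: list[str],
    noise_sd: float = 0.5,
    seed: int = 1234,
    unit_mix: dict[str, float] | None = None,
    relation_mix: dict[str, float] | None = None,
) -> SyntheticBenchmark:
    """Assign latent activities, labels and potency records to a library.

    With the default ``unit_mix``/``relation_mix`` of ``None``, every record
    is an exact ('=') nM measurement; pass the mixes from a
    :class:`GeneratorConfig` to interleave curation decoys. Replicate
    entries of the same list element beyond the first receive a small
    multiplicative value jitter.
    """
    if not smiles_list:
        raise InputError("smiles_list must be non-empty")
    canon = [canonical_smiles(s, context=f"entry {i}") for i, s in enumerate(smiles_list)]
    unique = list(dict.fromkeys(canon))

    noise_rng = _stream(seed, 1)
    rec_rng = _stream(seed, 2)

    d = _truth_descriptors(unique)
    mu, sd = d.mean(axis=0), d.std(axis=0)
    sd[sd == 0] = 1.0
    w = np.array(list(TRUTH_WEIGHTS.values()))
    z = (d - mu) / sd @ w + noise_rng.normal(0.0, noise_sd, size=len(unique))

    zc = z - np.median(z)
    sigma = z.std() or 1.0
    value_nM = 1000.0 * np.exp(-zc / sigma)
    labels = (zc > 0).astype(int)

    truth_labels = dict(zip(unique, (int(v) for v in labels)))
    base_value = dict(zip(unique, value_nM))

    units = ["nM"] if unit_mix is None else list(unit_mix)
    unit_p = None if unit_mix is None else np.array([unit_mix[u] for u in units])
    rels = ["="] if relation_mix is None else list(relation_mix)
    rel_p = None if relation_mix is None else np.array([relation_mix[r] for r in rels])

    mol_ids = {s: f"SYN-{i:06d}" for i, s in enumerate(unique)}
    seen: dict[str, int] = {}
    records: list[ActivityRecord] = []
    for raw, can in zip(smiles_list, canon):
        n_prior = seen.get(can, 0)
        seen[can] = n_prior + 1
        value = base_value[can]
        if n_prior:
            # replicate measurement: jitter the log-distance from the 1000 nM
            # boundary so replicates never cross the planted label boundary
            factor = float(np.exp(rec_rng.normal(0.0, 0.2)))
            value = 1000.0 * (value / 1000.0) ** factor
        unit = str(rec_rng.choice(units, p=unit_p)) if unit_mix else "nM"
        rel = str(rec_rng.choice(rels, p=rel_p)) if relation_mix else "="
        if unit == "uM":
            emitted, unit_str = value / 1000.0, "uM"
        elif unit == "other":
            emitted, unit_str = value, "ug.mL-1"
        else:
            emitted, unit_str = value, "nM"
        records.append(
            ActivityRecord(
                molecule_id=mol_ids[can],
                smiles=raw,
                standard_type="IC50",
                standard_relation=rel,
                standard_value=float(emitted),
                standard_units=unit_str,
            )
        )
    return SyntheticBenchmark(
        records=records,
        truth_labels=truth_labels,
        truth_weights=dict(TRUTH_WEIGHTS),
        seed=seed,
        noise_sd=noise_sd,
    )


def generate_benchmark(config: GeneratorConfig) -> SyntheticBenchmark:
    """Full draw: grammar library + planted activity + decoy-laden records."""
    library = generate_library(config)
    return plant_activity(
        library,
        noise_sd=config.noise_sd,
        seed=config.seed,
        unit_mix=config.unit_mix,
        relation_mix=config.relation_mix,
    )
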