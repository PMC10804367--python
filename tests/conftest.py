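"""Shared fixtures: synthetic benchmarks, fast member specs, oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import settings
from rdkit import Chem

from npjury.curation import curate
from npjury.descriptors import DescriptorCalculator
from npjury.fragments import Fragment
from npjury.jury_models import ClassifierSpec
from npjury.synthetic_data import GeneratorConfig, generate_benchmark

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


#: cheap member hyperparameters for tests that exercise machinery, not
#: the study configuration
def fast_specs(seed: int = 11) -> list[ClassifierSpec]:
    return [
        ClassifierSpec("gbt", {"tree_depth": 4, "n_trees": 80, "learning_rate": 0.1}, seed),
        ClassifierSpec("logreg", {"max_epochs": 100, "epsilon": 1e-5, "step_size": 0.1}, seed),
        ClassifierSpec("nbayes", {"probability_floor": 0.0}, seed),
    ]


@pytest.fixture(scope="session")
def benchmark_2000():
    """The study-scale benchmark draw: n=2000, seed 1234, default noise."""
    return generate_benchmark(GeneratorConfig(n_molecules=2000, seed=1234))


@pytest.fixture(scope="session")
def curated_2000(benchmark_2000):
    return curate(benchmark_2000.records)


@pytest.fixture(scope="session")
def matrix_labels_2000(curated_2000):
    """Raw (unnormalized) descriptor matrix and labels of the curated set."""
    matrix = DescriptorCalculator().fit_transform(curated_2000.smiles)
    labels = curated_2000.labels.loc[matrix.index].to_numpy()
    return matrix, labels


@pytest.fixture(scope="session")
def small_benchmark():
    """A cheap decoy-free draw for machinery tests."""
    cfg = GeneratorConfig(
        n_molecules=400,
        seed=11,
        duplicate_rate=0.0,
        unit_mix={"nM": 1.0, "uM": 0.0, "other": 0.0},
        relation_mix={"=": 1.0, ">": 0.0, "<": 0.0},
    )
    return generate_benchmark(cfg)


def brute_force_fragments(smiles: str, min_bonds: int = 4, max_bonds: int = 8) -> set[Fragment]:
    """Independent fragment oracle: exhaustive bond subsets + union-find
    connectivity + the aromatic-completeness rule, deduplicated by
    canonical subgraph SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    bonds = list(range(mol.GetNumBonds()))

    info = mol.GetRingInfo()
    arom_ring_of: dict[int, frozenset[int]] = {}
    for atom_ring, bond_ring in zip(info.AtomRings(), info.BondRings()):
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring):
            for a in atom_ring:
                if a not in arom_ring_of or len(bond_ring) < len(arom_ring_of[a]):
                    arom_ring_of[a] = frozenset(bond_ring)

    def connected(bond_ids) -> bool:
        parent: dict[int, int] = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for b in bond_ids:
            bond = mol.GetBondWithIdx(b)
            ra, rb = find(bond.GetBeginAtomIdx()), find(bond.GetEndAtomIdx())
            parent[ra] = rb
        roots = {find(a) for a in parent}
        return len(roots) == 1

    def aromatic_ok(bond_ids) -> bool:
        atoms = set()
        for b in bond_ids:
            bond = mol.GetBondWithIdx(b)
            atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        for a in atoms:
            if mol.GetAtomWithIdx(a).GetIsAromatic():
                ring = arom_ring_of.get(a)
                if ring is None or not ring <= set(bond_ids):
                    return False
        return True

    found: dict[str, Fragment] = {}
    for size in range(min_bonds, max_bonds + 1):
        for subset in combinations(bonds, size):
            if not connected(subset) or not aromatic_ok(subset):
                continue
            sub = Chem.PathToSubmol(mol, list(subset))
            smi = Chem.MolToSmiles(sub)
            atoms = set()
            for b in subset:
                bond = mol.GetBondWithIdx(b)
                atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            found.setdefault(smi, Fragment(smiles=smi, bond_count=size, atom_count=len(atoms)))
    return set(found.values())


@pytest.fixture
def fragment_oracle():
    return brute_force_fragments


def random_binary(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    return (rng.random(n) < p).astype(int)
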