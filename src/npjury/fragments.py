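"""Substructure fragment enumeration and strong/weak enrichment.

Each molecule is decomposed into all connected bond-subgraphs of 4-8 bonds
(ring closures included, so intact rings are legal fragments), identified
by the canonical SMILES of the subgraph with aromaticity inherited from
the parent. Fragments containing an *interrupted aromatic system* — an
aromatic atom whose smallest aromatic ring is not wholly inside the
fragment — are discarded.

Frequencies are molecule-level incidences: the number of molecules in a
set containing a fragment at least once, divided by the set size. The
enrichment ratio freq(strong) / freq(weak) ranks fragments by their
overrepresentation among strong modulators; fragments seen in only one
set are reported in side lists rather than given an infinite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem

from .chem import mol_from_smiles
from .errors import InputError

MIN_BONDS = 4
MAX_BONDS = 8


@dataclass(frozen=True)
class Fragment:
    """A connected bond-subgraph, identified by canonical SMILES."""

    smiles: str
    bond_count: int
    atom_count: int


def _aromatic_bond_rings(mol: Chem.Mol) -> dict[int, frozenset[int]]:
    """Map each aromatic atom to the bond set of its smallest aromatic ring."""
    info = mol.GetRingInfo()
    smallest: dict[int, frozenset[int]] = {}
    for atom_ring, bond_ring in zip(info.AtomRings(), info.BondRings()):
        if not all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring):
            continue
        bonds = frozenset(bond_ring)
        for idx in atom_ring:
            if idx not in smallest or len(bonds) < len(smallest[idx]):
                smallest[idx] = bonds
    return smallest


def _fragment_atoms(mol: Chem.Mol, bond_ids) -> set[int]:
    atoms: set[int] = set()
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return atoms


def aromatic_complete(mol: Chem.Mol, bond_ids, ring_map=None) -> bool:
    """True iff every aromatic atom in the subgraph brings its whole
    smallest aromatic ring along."""
    if ring_map is None:
        ring_map = _aromatic_bond_rings(mol)
    bonds = set(bond_ids)
    for idx in _fragment_atoms(mol, bond_ids):
        if not mol.GetAtomWithIdx(idx).GetIsAromatic():
            continue
        ring = ring_map.get(idx)
        if ring is None or not ring <= bonds:
            return False
    return True


def fragment_from_bonds(mol: Chem.Mol, bond_ids) -> Fragment:
    sub = Chem.PathToSubmol(mol, list(bond_ids))
    return Fragment(
        smiles=Chem.MolToSmiles(sub),
        bond_count=len(bond_ids),
        atom_count=len(_fragment_atoms(mol, bond_ids)),
    )


def enumerate_fragments(
    molecule: str | Chem.Mol, min_bonds: int = MIN_BONDS, max_bonds: int = MAX_BONDS
) -> set[Fragment]:
    """All aromatic-complete connected bond-subgraphs with ``min_bonds`` to
    ``max_bonds`` bonds, deduplicated by canonical fragment SMILES."""
    mol = mol_from_smiles(molecule) if isinstance(molecule, str) else molecule
    if mol.GetNumBonds() < min_bonds:
        return set()
    ring_map = _aromatic_bond_rings(mol)
    seen: dict[str, Fragment] = {}
    for tier in Chem.FindAllSubgraphsOfLengthMToN(mol, min_bonds, max_bonds):
        for bond_ids in tier:
            if not aromatic_complete(mol, bond_ids, ring_map):
                continue
            frag = fragment_from_bonds(mol, bond_ids)
            seen.setdefault(frag.smiles, frag)
    return set(seen.values())


@dataclass
class FragmentTable:
    """Molecule-level fragment incidence for one molecule set."""

    n_molecules: int
    counts: dict[str, int] = field(default_factory=dict)  # fragment smiles -> n containing

    def frequency(self, fragment_smiles: str) -> float:
        return self.counts.get(fragment_smiles, 0) / self.n_molecules

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fragment": smi, "n_containing": n, "frequency": n / self.n_molecules}
            for smi, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["fragment", "n_containing", "frequency"])


def fragment_frequencies(
    molecule_set, min_bonds: int = MIN_BONDS, max_bonds: int = MAX_BONDS
) -> FragmentTable:
    """Incidence table over a molecule set; a fragment occurring several
    times in one molecule counts once."""
    molecules = list(molecule_set)
    if not molecules:
        raise InputError("fragment frequencies need a non-empty molecule set")
    counts: dict[str, int] = {}
    for smi in molecules:
        for frag in enumerate_fragments(smi, min_bonds, max_bonds):
            counts[frag.smiles] = counts.get(frag.smiles, 0) + 1
    return FragmentTable(n_molecules=len(molecules), counts=counts)


@dataclass
class EnrichmentReport:
    """Per-fragment strong/weak frequency comparison, ranked by ratio."""

    ranked: pd.DataFrame     # fragment, n_strong, freq_strong, n_weak, freq_weak, ratio
    strong_only: list[str]
    weak_only: list[str]


def enrichment(strong: FragmentTable, weak: FragmentTable) -> EnrichmentReport:
    """Ratio freq(strong)/freq(weak) for fragments seen in both sets;
    one-set-only fragments go to the side lists (no finite ratio)."""
    if strong.n_molecules == 0 or weak.n_molecules == 0:
        raise InputError("enrichment needs two non-empty fragment tables")
    shared = sorted(set(strong.counts) & set(weak.counts))
    rows = []
    for smi in shared:
        fs, fw = strong.frequency(smi), weak.frequency(smi)
        rows.append(
            {
                "fragment": smi,
                "n_strong": strong.counts[smi],
                "freq_strong": fs,
                "n_weak": weak.counts[smi],
                "freq_weak": fw,
                "ratio": fs / fw,
            }
        )
    ranked = pd.DataFrame(
        rows, columns=["fragment", "n_strong", "freq_strong", "n_weak", "freq_weak", "ratio"]
    )
    if len(ranked):
        ranked = ranked.sort_values(["ratio", "fragment"], ascending=[False, True]).reset_index(
            drop=True
        )
    return EnrichmentReport(
        ranked=ranked,
        strong_only=sorted(set(strong.counts) - set(weak.counts)),
        weak_only=sorted(set(weak.counts) - set(strong.counts)),
    )
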