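"""Fingerprint similarity for novelty assessment of screening hits.

Two hashed fingerprint families, both folded to 2048 bits:

* ``path`` — linear-path (Daylight-style) fingerprints over bond paths of
  1-7 bonds;
* ``atom_pair`` — atom-pair features (atom type, atom type, topological
  distance) with distances 1-30.

Candidate novelty is judged by the best Tanimoto coefficient against a
reference set of known modulators: a low nearest-neighbor similarity in
both families marks a candidate as occupying new chemical space. The
Tanimoto of two all-zero vectors is defined as 1 (identical objects);
nearest-neighbor ties go to the earlier reference in input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .chem import mol_from_smiles
from .errors import InputError

N_BITS = 2048
FAMILIES = ("path", "atom_pair")
PATH_PARAMS = {"min_path": 1, "max_path": 7}
ATOM_PAIR_PARAMS = {"min_distance": 1, "max_distance": 30}


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary fingerprint with its family tag."""

    bits: tuple[int, ...]   # sorted indices of set bits
    family: str
    n_bits: int = N_BITS

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=bool)
        arr[list(self.bits)] = True
        return arr

    @property
    def popcount(self) -> int:
        return len(self.bits)


def _to_mol(molecule: str | Chem.Mol) -> Chem.Mol:
    return mol_from_smiles(molecule) if isinstance(molecule, str) else molecule


def path_fingerprint(molecule: str | Chem.Mol) -> Fingerprint:
    """Hashed linear-path fingerprint (paths of 1-7 bonds, 2048 bits)."""
    mol = _to_mol(molecule)
    bv = Chem.RDKFingerprint(
        mol, minPath=PATH_PARAMS["min_path"], maxPath=PATH_PARAMS["max_path"], fpSize=N_BITS
    )
    return Fingerprint(bits=tuple(bv.GetOnBits()), family="path")


def atom_pair_fingerprint(molecule: str | Chem.Mol) -> Fingerprint:
    """Hashed atom-pair fingerprint (topological distances 1-30, 2048 bits)."""
    mol = _to_mol(molecule)
    bv = rdMolDescriptors.GetHashedAtomPairFingerprintAsBitVect(
        mol,
        nBits=N_BITS,
        minLength=ATOM_PAIR_PARAMS["min_distance"],
        maxLength=ATOM_PAIR_PARAMS["max_distance"],
    )
    return Fingerprint(bits=tuple(bv.GetOnBits()), family="atom_pair")


_FP_FUNCS = {"path": path_fingerprint, "atom_pair": atom_pair_fingerprint}


def fingerprint(molecule: str | Chem.Mol, family: str) -> Fingerprint:
    if family not in _FP_FUNCS:
        raise InputError(f"unknown fingerprint family {family!r}; expected one of {FAMILIES}")
    return _FP_FUNCS[family](molecule)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two all-zero vectors score 1 by convention."""
    if fp_a.family != fp_b.family or fp_a.n_bits != fp_b.n_bits:
        raise InputError(
            f"incomparable fingerprints: {fp_a.family}/{fp_a.n_bits} vs {fp_b.family}/{fp_b.n_bits}"
        )
    a, b = set(fp_a.bits), set(fp_b.bits)
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def nearest_known(
    candidates,
    references,
    families: tuple[str, ...] = FAMILIES,
    candidate_ids=None,
    reference_ids=None,
) -> pd.DataFrame:
    """Exhaustive nearest-reference scan per candidate and family.

    Returns a frame (candidate, family, best_score, nearest_reference);
    ties are broken by reference input order.
    """
    candidates = list(candidates)
    references = list(references)
    if not candidates or not references:
        raise InputError("nearest_known needs non-empty candidate and reference sets")
    candidate_ids = list(candidate_ids) if candidate_ids is not None else candidates
    reference_ids = list(reference_ids) if reference_ids is not None else references

    rows = []
    for family in families:
        ref_fps = [fingerprint(r, family) for r in references]
        ref_matrix = np.stack([fp.to_array() for fp in ref_fps])
        for cand, cand_id in zip(candidates, candidate_ids):
            cand_arr = fingerprint(cand, family).to_array()
            inter = (ref_matrix & cand_arr).sum(axis=1)
            union = (ref_matrix | cand_arr).sum(axis=1)
            scores = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
            best = int(np.argmax(scores))  # first max: input-order tie-break
            rows.append(
                {
                    "candidate": cand_id,
                    "family": family,
                    "best_score": float(scores[best]),
                    "nearest_reference": reference_ids[best],
                }
            )
    return pd.DataFrame(rows, columns=["candidate", "family", "best_score", "nearest_reference"])
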