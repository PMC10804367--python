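"""Small RDKit helpers used by several stages.

Canonicalization policy: the molecule identity used throughout the package
is the canonical SMILES of the largest organic fragment (salt stripping by
heavy-atom count, ties broken by canonical SMILES order). Charges are left
as drawn; stereochemistry is whatever the toolkit canonicalization keeps.
"""

from __future__ import annotations

from rdkit import Chem, RDLogger

from .errors import InputError

# RDKit is chatty about odd valences in user input; errors are surfaced as
# exceptions by our own wrappers instead.
RDLogger.DisableLog("rdApp.*")


def mol_from_smiles(smiles: str, context: str | None = None) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`InputError` naming the entry."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise InputError(f"empty SMILES{f' ({context})' if context else ''}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" ({context})" if context else ""
        raise InputError(f"unparseable SMILES{where}: {smiles!r}")
    return mol


def _is_organic(frag: Chem.Mol) -> bool:
    return any(atom.GetAtomicNum() == 6 for atom in frag.GetAtoms())


def largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Strip salts/solvents: keep the fragment with the most heavy atoms,
    preferring carbon-containing fragments over purely inorganic ones."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    organic = [f for f in frags if _is_organic(f)] or list(frags)
    return max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def canonical_smiles(smiles: str, context: str | None = None) -> str:
    """Canonical SMILES of the largest organic fragment."""
    mol = mol_from_smiles(smiles, context)
    return Chem.MolToSmiles(largest_organic_fragment(mol))
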