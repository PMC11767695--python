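"""Shared small-molecule helpers built on RDKit.

Canonicalisation conventions used throughout the package:

* molecules are exchanged as canonical SMILES without stereochemistry
  (hydrolysis rules carry no stereo information, and product matching
  must not depend on drawn wedge bonds);
* multi-component inputs are reduced to their largest organic fragment
  before atom labelling (rules address the organic core, not counterions);
* atom indices are 0-based over heavy atoms in the canonical atom order
  of the parsed SMILES, hydrogens implicit.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

# RDKit is chatty about every sanitization failure; parse errors are
# reported through our own return values instead.
RDLogger.DisableLog("rdApp.*")

#: elements whose atoms are tracked for site-of-metabolism labelling.
#: Halogens share one class ("X"); sulfur and halogens only appear in the
#: global dataset because standalone S/X corpora are too small to train on.
ELEMENT_CLASS = {
    "N": "N",
    "O": "O",
    "C": "C",
    "S": "S",
    "F": "X",
    "Cl": "X",
    "Br": "X",
    "I": "X",
}

TRACKED_CLASSES = ("N", "O", "C", "S", "X")

#: small by-products of hydrolysis (water-derived CO2, ammonia, hydrogen
#: halides, hydroxylamine...).  They are kept in product listings but are
#: too unspecific to serve as evidence when matching rule output against
#: observed products.
INORGANIC_FRAGMENTS = frozenset(
    ["O=C=O", "N", "O", "F", "Cl", "Br", "I", "S", "NO", "O=S=O"]
)


class MoleculeError(ValueError):
    """Raised when a structure cannot be parsed or sanitized."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES to a sanitized RDKit molecule or raise MoleculeError."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonical_smiles(mol_or_smiles) -> str:
    """Canonical, stereo-stripped SMILES of a molecule or SMILES string."""
    if isinstance(mol_or_smiles, str):
        mol = mol_from_smiles(mol_or_smiles)
    else:
        mol = Chem.Mol(mol_or_smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def split_fragments(smiles: str) -> list[str]:
    """Split a dot-separated SMILES into canonical single-fragment SMILES."""
    mol = mol_from_smiles(smiles)
    return [canonical_smiles(f) for f in Chem.GetMolFrags(mol, asMols=True)]


def is_organic(smiles: str) -> bool:
    """True if the fragment is specific enough to count as product evidence."""
    if smiles in INORGANIC_FRAGMENTS:
        return False
    mol = mol_from_smiles(smiles)
    return any(a.GetSymbol() == "C" for a in mol.GetAtoms())


def largest_organic_fragment(smiles: str) -> str:
    """Largest fragment by heavy-atom count, preferring carbon-containing ones.

    Ties break on canonical SMILES order so the choice is deterministic.
    """
    frags = split_fragments(smiles)
    if not frags:
        raise MoleculeError(f"no fragments in {smiles!r}")

    def key(f: str):
        m = mol_from_smiles(f)
        has_c = any(a.GetSymbol() == "C" for a in m.GetAtoms())
        return (has_c, m.GetNumHeavyAtoms(), f)

    return max(frags, key=key)


def atom_orbits(mol: Chem.Mol) -> list[int]:
    """Symmetry-orbit id per atom (automorphic atoms share an id)."""
    return list(Chem.CanonicalRankAtoms(mol, breakTies=False))


def heavy_atom_count(smiles: str) -> int:
    return mol_from_smiles(smiles).GetNumHeavyAtoms()
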