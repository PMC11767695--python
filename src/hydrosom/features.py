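"""Per-atom feature vectors: circular environment fingerprints + descriptors.

Each tracked heavy atom is represented by a 1024-bit Morgan-style circular
fingerprint of the environments rooted at that atom up to radius 3 bonds,
concatenated with eight interpretable atomic descriptors, for a fixed
feature length of 1032.  Bit positions are a property of the hashing
dialect (RDKit Morgan generator) and are therefore recorded in model
metadata; vectors from other toolkits are not interchangeable.

Descriptor set (order is part of the feature contract, see
DESCRIPTOR_NAMES): Gasteiger sigma partial charge (e), Crippen atomic logP
contribution, Crippen atomic molar-refractivity contribution (a
polarizability surrogate), Pauling electronegativity of the element,
heavy-atom degree, attached hydrogen count, aromaticity indicator (0/1)
and smallest-ring size (0 if acyclic).  The set is configurable in the
sense that the contract is versioned: models refuse feature vectors from a
different feature version.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdFingerprintGenerator, rdMolDescriptors

from .chem import ELEMENT_CLASS, MoleculeError, mol_from_smiles

FP_BITS = 1024
FP_RADIUS = 3
DESCRIPTOR_NAMES = (
    "gasteiger_charge",
    "crippen_logp",
    "crippen_mr",
    "pauling_en",
    "heavy_degree",
    "attached_h",
    "is_aromatic",
    "min_ring_size",
)
N_FEATURES = FP_BITS + len(DESCRIPTOR_NAMES)
FEATURE_VERSION = "rdkit-morgan-1024-r3/descr8-v1"
FEATURE_COLUMNS = [f"fp_{i}" for i in range(FP_BITS)] + [f"d_{n}" for n in DESCRIPTOR_NAMES]

# Pauling electronegativities for the elements the corpus can contain.
_PAULING_EN = {
    "H": 2.20, "B": 2.04, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
    "Si": 1.90, "P": 2.19, "S": 2.58, "Cl": 3.16, "Br": 2.96, "I": 2.66,
}

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


class FeatureError(ValueError):
    """Featurization failure (bad atom index, divergent charges...)."""


def atom_environment_fingerprint(
    mol: Chem.Mol, atom_index: int, radius: int = FP_RADIUS, n_bits: int = FP_BITS
) -> np.ndarray:
    """1024-bit binary vector of circular environments rooted at one atom."""
    if not (0 <= atom_index < mol.GetNumAtoms()):
        raise FeatureError(
            f"atom index {atom_index} out of range for {mol.GetNumAtoms()}-atom molecule"
        )
    if radius == FP_RADIUS and n_bits == FP_BITS:
        gen = _fp_generator
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol, fromAtoms=[atom_index])
    vec = np.zeros(n_bits, dtype=np.uint8)
    vec[list(bv.GetOnBits())] = 1
    return vec


def _molecule_descriptor_table(mol: Chem.Mol) -> np.ndarray:
    """Descriptor rows for every atom of a molecule (computed once per mol)."""
    AllChem.ComputeGasteigerCharges(mol)
    crippen = rdMolDescriptors._CalcCrippenContribs(mol)
    ring_info = mol.GetRingInfo()
    rows = np.empty((mol.GetNumAtoms(), len(DESCRIPTOR_NAMES)), dtype=np.float64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(q):
            raise FeatureError(
                f"Gasteiger charge did not converge for {Chem.MolToSmiles(mol)!r}"
            )
        ring_sizes = [s for s in range(3, 13) if ring_info.IsAtomInRingOfSize(i, s)]
        rows[i] = (
            q,
            crippen[i][0],
            crippen[i][1],
            _PAULING_EN.get(atom.GetSymbol(), 0.0),
            atom.GetDegree(),
            atom.GetTotalNumHs(),
            1.0 if atom.GetIsAromatic() else 0.0,
            float(min(ring_sizes)) if ring_sizes else 0.0,
        )
    return rows


def atom_descriptors(mol: Chem.Mol, atom_index: int) -> np.ndarray:
    """The 8 interpretable atomic descriptors for one atom."""
    if not (0 <= atom_index < mol.GetNumAtoms()):
        raise FeatureError(f"atom index {atom_index} out of range")
    return _molecule_descriptor_table(mol)[atom_index]


def featurize(
    mol_or_smiles,
    atom_classes: tuple[str, ...] | None = None,
    atom_indices: list[int] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Feature matrix for the requested atoms of one molecule.

    Returns ``(X, indices)`` where ``X`` has one 1032-length row per
    selected heavy atom.  Selection is either explicit ``atom_indices`` or
    all atoms whose element class is in ``atom_classes`` (all tracked
    classes when None).
    """
    mol = mol_from_smiles(mol_or_smiles) if isinstance(mol_or_smiles, str) else mol_or_smiles
    if atom_indices is None:
        wanted = set(atom_classes) if atom_classes is not None else None
        atom_indices = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if ELEMENT_CLASS.get(a.GetSymbol()) is not None
            and (wanted is None or ELEMENT_CLASS[a.GetSymbol()] in wanted)
        ]
    if not atom_indices:
        return np.empty((0, N_FEATURES), dtype=np.float64), []
    desc = _molecule_descriptor_table(mol)
    X = np.empty((len(atom_indices), N_FEATURES), dtype=np.float64)
    for row, idx in enumerate(atom_indices):
        X[row, :FP_BITS] = atom_environment_fingerprint(mol, idx)
        X[row, FP_BITS:] = desc[idx]
    return X, list(atom_indices)


def featurize_table(table: pd.DataFrame) -> np.ndarray:
    """Feature matrix for a labelled atom table (one row per table row).

    The table needs ``parent_smiles`` and ``atom_index`` columns; parents
    are featurized once each and rows gathered in table order.
    """
    if table.empty:
        return np.empty((0, N_FEATURES), dtype=np.float64)
    table = table.reset_index(drop=True)
    X = np.empty((len(table), N_FEATURES), dtype=np.float64)
    for smiles, group in table.groupby("parent_smiles", sort=False):
        rows, _ = featurize(smiles, atom_indices=group["atom_index"].tolist())
        X[group.index.to_numpy()] = rows
    return X


def feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Labelled atom table joined with its feature columns (export shape)."""
    X = featurize_table(table.reset_index(drop=True))
    feats = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    return pd.concat([table.reset_index(drop=True), feats], axis=1)
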