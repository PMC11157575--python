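"""Fixed input descriptors for atoms, bonds and whole molecules.

Atom descriptors: atomic number (one-hot over C/H/O/N/S/P plus one shared
"other" bucket — halogens, metals etc. all map to the same encoding so the
input dimensionality stays small), degree, formal charge, chirality tag,
number of bonded hydrogens, hybridization, aromaticity, ring membership, and
atomic mass scaled by 1/100.

Bond descriptors: bond type (single/double/triple/aromatic), conjugation,
ring membership, stereochemistry.

Categorical descriptors are one-hot with an explicit category list (the
convention of message-passing featurizers); mass is the single scalar.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .errors import DataError

_ELEMENTS = ("C", "H", "O", "N", "S", "P")  # + shared "other" bucket
_DEGREES = (0, 1, 2, 3, 4, 5)
_CHARGES = (-2, -1, 0, 1, 2)
_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
)
_NUM_HS = (0, 1, 2, 3, 4)
_HYBRIDIZATIONS = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_BOND_STEREO = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
)

ATOM_FDIM = (
    (len(_ELEMENTS) + 1) + (len(_DEGREES) + 1) + (len(_CHARGES) + 1)
    + (len(_CHIRAL_TAGS) + 1) + (len(_NUM_HS) + 1) + (len(_HYBRIDIZATIONS) + 1)
    + 2 + 1
)
BOND_FDIM = (len(_BOND_TYPES) + 1) + 2 + (len(_BOND_STEREO) + 1)
MOL_FDIM = 6


def _one_hot(value, categories) -> list[float]:
    # trailing slot is the catch-all for values outside the category list
    vec = [0.0] * (len(categories) + 1)
    try:
        vec[list(categories).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(mol: Chem.Mol, atom_index: int) -> np.ndarray:
    """Descriptor vector x_v of one heavy atom; length ``ATOM_FDIM``."""
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    a = mol.GetAtomWithIdx(atom_index)
    parts = (
        _one_hot(a.GetSymbol(), _ELEMENTS)
        + _one_hot(a.GetDegree(), _DEGREES)
        + _one_hot(a.GetFormalCharge(), _CHARGES)
        + _one_hot(a.GetChiralTag(), _CHIRAL_TAGS)
        + _one_hot(a.GetTotalNumHs(), _NUM_HS)
        + _one_hot(a.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if a.GetIsAromatic() else 0.0, 1.0 if a.IsInRing() else 0.0]
        + [a.GetMass() / 100.0]
    )
    return np.asarray(parts, dtype=np.float64)


#: Fixed encoding of a hydrogen atom, used as the partner-atom features of the
#: i-H pseudo-bonds (hydrogens are not expanded into graph vertices).
def hydrogen_features() -> np.ndarray:
    parts = (
        _one_hot("H", _ELEMENTS)
        + _one_hot(1, _DEGREES)
        + _one_hot(0, _CHARGES)
        + _one_hot(Chem.ChiralType.CHI_UNSPECIFIED, _CHIRAL_TAGS)
        + _one_hot(0, _NUM_HS)
        + _one_hot(Chem.HybridizationType.S, _HYBRIDIZATIONS)
        + [0.0, 0.0]
        + [1.008 / 100.0]
    )
    return np.asarray(parts, dtype=np.float64)


def bond_features(mol: Chem.Mol, i: int, j: int) -> np.ndarray:
    """Descriptor vector e_vw of the bond between heavy atoms ``i`` and
    ``j``; identical for both orientations.  Length ``BOND_FDIM``."""
    b = mol.GetBondBetweenAtoms(i, j)
    if b is None:
        raise DataError(f"no bond between atoms {i} and {j}")
    parts = (
        _one_hot(b.GetBondType(), _BOND_TYPES)
        + [1.0 if b.GetIsConjugated() else 0.0, 1.0 if b.IsInRing() else 0.0]
        + _one_hot(b.GetStereo(), _BOND_STEREO)
    )
    return np.asarray(parts, dtype=np.float64)


def hbond_features() -> np.ndarray:
    """Descriptor vector of an i-H pseudo-bond: a plain single bond with no
    conjugation, ring membership or stereochemistry."""
    parts = (
        _one_hot(Chem.BondType.SINGLE, _BOND_TYPES)
        + [0.0, 0.0]
        + _one_hot(Chem.BondStereo.STEREONONE, _BOND_STEREO)
    )
    return np.asarray(parts, dtype=np.float64)


def molecular_descriptors(mol: Chem.Mol) -> np.ndarray:
    """The six fixed-rule molecular descriptors: molecular weight, H-bond
    acceptor count, H-bond donor count, Crippen logP, topological polar
    surface area, Labute approximate surface area."""
    try:
        vec = np.array(
            [
                Descriptors.MolWt(mol),
                Lipinski.NumHAcceptors(mol),
                Lipinski.NumHDonors(mol),
                Crippen.MolLogP(mol),
                rdMolDescriptors.CalcTPSA(mol),
                rdMolDescriptors.CalcLabuteASA(mol),
            ],
            dtype=np.float64,
        )
    except Exception as exc:  # pragma: no cover - rdkit failure paths vary
        raise DataError(f"molecular descriptor computation failed: {exc}") from exc
    if not np.all(np.isfinite(vec)):
        raise DataError("non-finite molecular descriptor")
    return vec
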