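"""Annotated structure data: molecules, bond-of-metabolism (BOM) annotations,
site-of-metabolism (SOM) labels, and molecule-level dataset splits.

A *BOM* is the bond-centric annotation carried by the source SDF files: a pair
of heavy atoms, a heavy-atom-to-hydrogen bond, or a lone-pair reaction on
S/N/P.  A *SOM* is the unified site key the classifier consumes: an atom, a
heavy-atom bond, or the pseudo-bond between a heavy atom and its (implicit)
hydrogens.  Atoms and bonds share one key space because a single discriminator
scores both.

Labeling rules
--------------
1. A BOM between two heavy atoms ``i-j`` marks the bond site ``(i, j)``
   positive.
2. A BOM replacing a hydrogen on heavy atom ``i`` marks *both* the atom site
   ``i`` and the ``i``-H pseudo-bond site positive (the reaction involves the
   atom and its bond to hydrogen).
3. A lone-pair reaction on S, P or N marks that atom site positive.

Everything else in the candidate universe (all heavy atoms, all heavy-atom
bonds, one i-H pseudo-bond per hydrogen-bearing heavy atom) is negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: The nine human CYP450 isoforms handled throughout the package.
ISOFORMS: tuple[str, ...] = (
    "1A2", "2A6", "2B6", "2C8", "2C9", "2C19", "2D6", "2E1", "3A4",
)

#: Elements encoded individually by the featurizer; everything else collapses
#: to a shared "other" bucket.
ELEMENT_ALPHABET: tuple[str, ...] = ("C", "H", "O", "N", "S", "P")

_LONE_PAIR_ELEMENTS = frozenset({"S", "P", "N"})


# ---------------------------------------------------------------------------
# Site keys
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SiteKey:
    """A candidate metabolic site: an atom, a heavy-atom bond, or the
    pseudo-bond between heavy atom ``a`` and its hydrogens.

    ``kind`` is one of ``"atom"``, ``"bond"``, ``"hbond"``.  Bond pairs are
    stored with the smaller atom index first; ``b`` is -1 for non-bond kinds.
    Hydrogens are never referenced by index: implicit-H graphs are assumed and
    rule-2 sites are keyed once per heavy atom, not once per hydrogen.
    """

    kind: str
    a: int
    b: int = -1

    def __post_init__(self) -> None:
        if self.kind not in ("atom", "bond", "hbond"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.kind == "bond":
            if self.b < 0:
                raise ValueError("bond site needs two atom indices")
            if self.a > self.b:
                lo, hi = self.b, self.a
                object.__setattr__(self, "a", lo)
                object.__setattr__(self, "b", hi)
        elif self.b != -1:
            raise ValueError(f"{self.kind} site takes a single atom index")

    @staticmethod
    def atom(i: int) -> "SiteKey":
        return SiteKey("atom", i)

    @staticmethod
    def bond(i: int, j: int) -> "SiteKey":
        lo, hi = (i, j) if i <= j else (j, i)
        return SiteKey("bond", lo, hi)

    @staticmethod
    def hbond(i: int) -> "SiteKey":
        return SiteKey("hbond", i)

    def atoms(self) -> tuple[int, ...]:
        return (self.a, self.b) if self.kind == "bond" else (self.a,)


#: BOM descriptors as parsed from annotations: ("bond", i, j) for a heavy-atom
#: pair, ("h", i) for an i-H bond, ("lp", i) for a lone-pair reaction.
Bom = tuple


# ---------------------------------------------------------------------------
# Molecule records
# ---------------------------------------------------------------------------

@dataclass
class MoleculeRecord:
    """A parsed molecule plus its per-isoform BOM annotations.

    ``mol`` is an RDKit molecule with implicit hydrogens; ``isoform_boms``
    maps isoform name -> frozenset of BOM descriptors (0-based atom indices).
    """

    mol_id: str
    mol: Chem.Mol
    isoform_boms: dict[str, frozenset[Bom]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iso in self.isoform_boms:
            if iso not in ISOFORMS:
                raise ConfigError(f"{self.mol_id}: unknown isoform {iso!r}")

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


def record_from_smiles(
    smiles: str,
    mol_id: str,
    isoform_boms: Mapping[str, Iterable[Bom]] | None = None,
) -> MoleculeRecord:
    """Build a :class:`MoleculeRecord` from a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"{mol_id}: unparsable SMILES {smiles!r}")
    boms = {k: frozenset(v) for k, v in (isoform_boms or {}).items()}
    return MoleculeRecord(mol_id=mol_id, mol=mol, isoform_boms=boms)


def candidate_sites(mol: Chem.Mol) -> list[SiteKey]:
    """The full candidate-site universe of a molecule: every heavy atom,
    every heavy-atom bond, and one i-H pseudo-bond per hydrogen-bearing heavy
    atom.  Order: atoms, bonds, hbonds (each ascending)."""
    sites: list[SiteKey] = [SiteKey.atom(a.GetIdx()) for a in mol.GetAtoms()]
    for b in mol.GetBonds():
        sites.append(SiteKey.bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
    for a in mol.GetAtoms():
        if a.GetTotalNumHs() > 0:
            sites.append(SiteKey.hbond(a.GetIdx()))
    return sites


# ---------------------------------------------------------------------------
# SOM labeling
# ---------------------------------------------------------------------------

@dataclass
class SomLabelSet:
    """Per-isoform labels over the candidate sites of one molecule."""

    mol_id: str
    isoform: str
    sites: list[SiteKey]
    labels: dict[SiteKey, bool]

    @property
    def positives(self) -> set[SiteKey]:
        return {s for s, pos in self.labels.items() if pos}

    @property
    def n_positive(self) -> int:
        return sum(self.labels.values())

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def y(self) -> np.ndarray:
        """Label vector aligned with ``sites``."""
        return np.array([self.labels[s] for s in self.sites], dtype=np.int64)


def label_soms(record: MoleculeRecord, isoform: str) -> SomLabelSet:
    """Convert the BOM annotations of ``record`` for ``isoform`` into SOM
    labels over the molecule's full candidate-site universe."""
    if isoform not in ISOFORMS:
        raise ConfigError(f"unknown isoform {isoform!r}")
    mol = record.mol
    n = mol.GetNumAtoms()
    sites = candidate_sites(mol)
    labels: dict[SiteKey, bool] = {s: False for s in sites}

    def _check_atom(i: int) -> None:
        if not (0 <= i < n):
            raise DataError(
                f"{record.mol_id}: BOM references atom {i} "
                f"but molecule has {n} heavy atoms"
            )

    for bom in record.isoform_boms.get(isoform, frozenset()):
        kind = bom[0]
        if kind == "bond":
            _, i, j = bom
            _check_atom(i)
            _check_atom(j)
            key = SiteKey.bond(i, j)
            if key not in labels:
                raise DataError(
                    f"{record.mol_id}: BOM bond {i}-{j} does not exist"
                )
            labels[key] = True
        elif kind == "h":
            (_, i) = bom
            _check_atom(i)
            if mol.GetAtomWithIdx(i).GetTotalNumHs() == 0:
                raise DataError(
                    f"{record.mol_id}: i-H BOM on atom {i} which bears no H"
                )
            labels[SiteKey.atom(i)] = True
            labels[SiteKey.hbond(i)] = True
        elif kind == "lp":
            (_, i) = bom
            _check_atom(i)
            sym = mol.GetAtomWithIdx(i).GetSymbol()
            if sym not in _LONE_PAIR_ELEMENTS:
                raise DataError(
                    f"{record.mol_id}: lone-pair BOM on {sym} atom {i}; "
                    "only S, P and N have lone-pair reactions"
                )
            labels[SiteKey.atom(i)] = True
        else:
            raise DataError(f"{record.mol_id}: unknown BOM kind {kind!r}")
    return SomLabelSet(record.mol_id, isoform, sites, labels)


# ---------------------------------------------------------------------------
# Annotated SDF I/O
# ---------------------------------------------------------------------------
# The upstream annotation dialect is undocumented, so the file layout is kept
# behind one seam: a property per isoform (default name "BOM_<isoform>")
# whose value is a whitespace/;-separated token list with 1-based indices:
#   "3-4"  heavy-atom bond,  "5-H"  hydrogen on atom 5,  "7-LP"  lone pair.
# A user-supplied ``isoform_field_map`` adapts other layouts.

def default_field_map() -> dict[str, str]:
    return {iso: f"BOM_{iso}" for iso in ISOFORMS}


def _parse_bom_tokens(text: str, mol_id: str) -> frozenset[Bom]:
    boms: set[Bom] = set()
    for token in text.replace(";", " ").replace(",", " ").split():
        parts = token.split("-")
        if len(parts) != 2:
            raise DataError(f"{mol_id}: malformed BOM token {token!r}")
        left, right = parts
        try:
            i = int(left) - 1
        except ValueError as exc:
            raise DataError(f"{mol_id}: malformed BOM token {token!r}") from exc
        if right.upper() == "H":
            boms.add(("h", i))
        elif right.upper() == "LP":
            boms.add(("lp", i))
        else:
            try:
                j = int(right) - 1
            except ValueError as exc:
                raise DataError(
                    f"{mol_id}: malformed BOM token {token!r}"
                ) from exc
            lo, hi = (i, j) if i <= j else (j, i)
            boms.add(("bond", lo, hi))
    return frozenset(boms)


def _format_bom_tokens(boms: Iterable[Bom]) -> str:
    tokens = []
    for bom in sorted(boms):
        if bom[0] == "bond":
            tokens.append(f"{bom[1] + 1}-{bom[2] + 1}")
        elif bom[0] == "h":
            tokens.append(f"{bom[1] + 1}-H")
        elif bom[0] == "lp":
            tokens.append(f"{bom[1] + 1}-LP")
        else:
            raise ValueError(f"unknown BOM kind {bom[0]!r}")
    return " ".join(tokens)


def read_annotated_sdf(
    path,
    isoform_field_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> list[MoleculeRecord]:
    """Read an SDF whose entries carry per-isoform BOM annotation properties.

    Malformed entries are logged and dropped (``strict=True`` raises instead);
    an ``isoform_field_map`` naming an unknown isoform raises
    :class:`ConfigError` before any parsing.
    """
    fmap = dict(isoform_field_map) if isoform_field_map else default_field_map()
    for iso in fmap:
        if iso not in ISOFORMS:
            raise ConfigError(f"isoform_field_map names unknown isoform {iso!r}")

    records: list[MoleculeRecord] = []
    import os

    if os.path.getsize(path) == 0:
        return records
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            msg = f"SDF entry {idx}: unparsable structure, skipped"
            if strict:
                raise DataError(msg)
            logger.warning(msg)
            continue
        mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not mol_id:
            mol_id = f"mol{idx}"
        try:
            boms = {
                iso: _parse_bom_tokens(mol.GetProp(prop), mol_id)
                for iso, prop in fmap.items()
                if mol.HasProp(prop)
            }
            records.append(MoleculeRecord(mol_id, mol, boms))
        except DataError:
            if strict:
                raise
            logger.warning("SDF entry %d (%s): bad annotation, skipped", idx, mol_id)
    return records


def write_annotated_sdf(records: Sequence[MoleculeRecord], path) -> None:
    """Write records to SDF with BOM annotations in the package dialect."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.mol_id)
            for iso, boms in sorted(rec.isoform_boms.items()):
                mol.SetProp(f"BOM_{iso}", _format_bom_tokens(boms))
            writer.write(mol)
    finally:
        writer.close()


def labels_to_frame(label_sets: Iterable[SomLabelSet]) -> pd.DataFrame:
    """Flatten label sets to a table: mol_id, isoform, site_kind, atoms, label."""
    rows = []
    for ls in label_sets:
        for site in ls.sites:
            rows.append(
                {
                    "mol_id": ls.mol_id,
                    "isoform": ls.isoform,
                    "site_kind": site.kind,
                    "atoms": "-".join(str(a) for a in site.atoms()),
                    "label": int(ls.labels[site]),
                }
            )
    return pd.DataFrame(rows, columns=["mol_id", "isoform", "site_kind", "atoms", "label"])


# ---------------------------------------------------------------------------
# Splits and count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    """A molecule-level train/validation partition."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train and validation ids overlap")


def split_by_molecule(
    records: Sequence[MoleculeRecord], ratio: float = 0.8, seed: int = 0
) -> DatasetSplit:
    """Deterministic train/validation split at molecule granularity.

    Site labels of one molecule never straddle the split.  Train size is
    ``round(ratio * N)`` (half away from zero), clamped so both sides are
    non-empty.
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigError(f"split ratio must be in (0,1), got {ratio}")
    if len(records) < 2:
        raise DataError("need at least 2 molecules to split")
    ids = [r.mol_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate mol_ids; cannot split by molecule")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(ratio * len(ids) + 0.5))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    val = tuple(ids[i] for i in sorted(order[n_train:]))
    return DatasetSplit(train, val, seed)


def som_count_table(
    records: Sequence[MoleculeRecord],
    isoforms: Sequence[str] = ISOFORMS,
) -> pd.DataFrame:
    """Per-isoform reactant / SOM / non-SOM counts.

    A molecule counts as a reactant for an isoform iff it has at least one
    positive SOM for it; SOM and non-SOM counts are accumulated over those
    reactant molecules only.
    """
    out = {}
    for iso in isoforms:
        reactants = soms = non = 0
        for rec in records:
            ls = label_soms(rec, iso)
            npos = ls.n_positive
            if npos > 0:
                reactants += 1
                soms += npos
                non += ls.n_negative
        out[iso] = {"reactants": reactants, "soms": soms, "non_soms": non}
    return pd.DataFrame(out).T[["reactants", "soms", "non_soms"]]
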