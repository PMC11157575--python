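"""Deterministic synthetic data: valid small molecules with planted SOM rules.

Molecules are assembled from a fragment grammar — sampled ring systems and
chains plus substituents joined by single bonds — so every output is a
sanitizable, valence-correct structure of 5-25 heavy atoms over C/H/O/N/S/P.
Random graphs would mostly test the sanitizer; a grammar tests the pipeline.

A :class:`PlantedRule` marks sites positive wherever a descriptor-level
predicate holds (e.g. "every sulfur atom"), optionally flipped with
probability epsilon.  Planted annotations are emitted in the same BOM dialect
the SDF reader consumes, so labels round-trip exactly.  The rules are
deliberately recoverable from the input descriptors: a trainable pipeline
must reach high held-out Jaccard on them, and must collapse to baseline when
the labels are permuted.  None of this mimics true CYP450 regioselectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from .chem import Bom, MoleculeRecord, record_from_smiles
from .errors import ConfigError

_SCAFFOLDS = (
    "c1ccccc1",      # benzene
    "c1ccncc1",      # pyridine
    "c1ccoc1",       # furan
    "c1ccsc1",       # thiophene
    "C1CCCCC1",      # cyclohexane
    "C1CCOC1",       # tetrahydrofuran
    "C1CCNCC1",      # piperidine
    "CCCCC",         # pentane
    "CCC(C)C",       # isopentane
)

_SUBSTITUENTS = (
    "C", "CC", "O", "OC", "N", "NC", "SC", "S", "C(C)O", "CN", "C=C",
    "C(=O)O", "OP(=O)(O)O",
)


def _attachable(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetSymbol() in ("C", "N")
    ]


def make_molecules(
    n: int,
    seed: int = 0,
    max_heavy: int = 25,
) -> list[MoleculeRecord]:
    """Generate ``n`` deterministic, valence-correct small molecules."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    k = 0
    while len(records) < n:
        scaffold = Chem.MolFromSmiles(_SCAFFOLDS[rng.integers(len(_SCAFFOLDS))])
        mol = Chem.RWMol(scaffold)
        n_subs = int(rng.integers(1, 5))
        for _ in range(n_subs):
            sub = Chem.MolFromSmiles(_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))])
            if mol.GetNumAtoms() + sub.GetNumAtoms() > max_heavy:
                break
            hosts = _attachable(mol)
            if not hosts:
                break
            host = int(hosts[rng.integers(len(hosts))])
            offset = mol.GetNumAtoms()
            combined = Chem.RWMol(Chem.CombineMols(mol, sub))
            combined.AddBond(host, offset, Chem.BondType.SINGLE)
            try:
                probe = combined.GetMol()
                Chem.SanitizeMol(probe)
            except Exception:
                continue
            mol = Chem.RWMol(probe)
        final = mol.GetMol()
        try:
            Chem.SanitizeMol(final)
        except Exception:  # pragma: no cover - grammar keeps molecules valid
            continue
        if final.GetNumAtoms() < 5:
            continue
        smiles = Chem.MolToSmiles(final)
        records.append(record_from_smiles(smiles, f"syn{k:04d}"))
        k += 1
    return records


# ---------------------------------------------------------------------------
# Planted rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRule:
    """A synthetic ground truth: ``predicate(mol)`` returns the positive BOM
    descriptors; each candidate site's membership is flipped with probability
    ``epsilon``."""

    name: str
    predicate: Callable[[Chem.Mol], set[Bom]]
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 0.5:
            raise ConfigError("epsilon must be in [0, 0.5)")


def _rule_sulfur(mol: Chem.Mol) -> set[Bom]:
    return {("lp", a.GetIdx()) for a in mol.GetAtoms() if a.GetSymbol() == "S"}


def _rule_aromatic_ch_next_to_o(mol: Chem.Mol) -> set[Bom]:
    out: set[Bom] = set()
    for a in mol.GetAtoms():
        if (
            a.GetSymbol() == "C" and a.GetIsAromatic() and a.GetTotalNumHs() > 0
            and any(n.GetSymbol() == "O" for n in a.GetNeighbors())
        ):
            out.add(("h", a.GetIdx()))
    return out


def _rule_c_o_bonds(mol: Chem.Mol) -> set[Bom]:
    out: set[Bom] = set()
    for b in mol.GetBonds():
        syms = {b.GetBeginAtom().GetSymbol(), b.GetEndAtom().GetSymbol()}
        if syms == {"C", "O"}:
            i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            out.add(("bond", i, j))
    return out


BUILTIN_RULES: dict[str, Callable[[Chem.Mol], set[Bom]]] = {
    "sulfur_atoms": _rule_sulfur,
    "aromatic_ch_next_to_o": _rule_aromatic_ch_next_to_o,
    "c_o_bonds": _rule_c_o_bonds,
}


def builtin_rule(name: str, epsilon: float = 0.0) -> PlantedRule:
    if name not in BUILTIN_RULES:
        raise ConfigError(f"unknown builtin rule {name!r}")
    return PlantedRule(name, BUILTIN_RULES[name], epsilon)


def _candidate_boms(mol: Chem.Mol) -> list[Bom]:
    """The BOM descriptor universe over which noise flips act."""
    out: list[Bom] = []
    for a in mol.GetAtoms():
        if a.GetSymbol() in ("S", "N", "P"):
            out.append(("lp", a.GetIdx()))
        if a.GetTotalNumHs() > 0:
            out.append(("h", a.GetIdx()))
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        out.append(("bond", i, j))
    return out


def plant_soms(
    molecules: Sequence[MoleculeRecord],
    rule: PlantedRule,
    isoform: str = "3A4",
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Annotate molecules with the rule's positives (noise-flipped with
    probability epsilon) as BOMs for ``isoform``."""
    rng = np.random.default_rng(seed)
    out = []
    for rec in molecules:
        positives = rule.predicate(rec.mol)
        chosen: set[Bom] = set()
        for bom in _candidate_boms(rec.mol):
            is_pos = bom in positives
            if rule.epsilon > 0 and rng.random() < rule.epsilon:
                is_pos = not is_pos
            if is_pos:
                chosen.add(bom)
        boms = dict(rec.isoform_boms)
        boms[isoform] = frozenset(chosen)
        out.append(MoleculeRecord(rec.mol_id, rec.mol, boms))
    return out
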