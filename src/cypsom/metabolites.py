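"""Deterministic phase-I metabolite generation from called SOMs.

Each called site maps to at most one reaction archetype, applied as an
explicit graph edit at that site (not a global pattern match):

Atom sites
    * S / N / P -> oxide (N as the charge-separated N-oxide).
    * aromatic C bearing H -> hydroxylation.
    * non-aromatic C with N/O neighbours -> cleave every single bond from
      that C to N/O (dealkylation); if the molecule falls into fragments,
      the cleaved carbon is further oxidised to the corresponding carbonyl
      (aldehyde or ketone by remaining H count) and every fragment is a
      product; if the molecule stays whole (ring), no product.

Bond sites
    * i-H pseudo-bond on a C next to N/O -> delegated to the atom rule on
      that C; any other C-H -> hydroxylation.
    * C=C -> epoxidation.
    * C-O with terminal O -> oxidation of the carbinol to the carbonyl;
      C-O inside an ether -> dealkylation at the carbon.
    * i-O with i in {S,N,P}: one O -> cleave it; several O on S/P -> cleave
      one; several O on N -> reduce to the primary amine (nitro -> NH2).
    * a ring whose bonds are all called -> aromatic/non-aromatic ring
      interconversion (checked once per ring).

Products are sanitised, canonicalised, deduplicated; single-step only
(products are not recursively metabolised).  A YAML manifest of the rules
with SMIRKS-style summaries ships in ``data/reaction_rules.yaml``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem

from .chem import SiteKey

logger = logging.getLogger(__name__)

_SNP = {"S", "N", "P"}


@dataclass(frozen=True)
class Product:
    smiles: str
    site: SiteKey
    rule: str


@dataclass
class MetaboliteSet:
    """Deduplicated single-step products of one parent molecule."""

    parent_id: str
    products: list[Product] = field(default_factory=list)

    def smiles(self) -> set[str]:
        return {p.smiles for p in self.products}


def _finalize(mol: Chem.Mol, site: SiteKey, rule: str) -> list[Product]:
    """Sanitize, split fragments, drop trivial ones, canonicalize."""
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        logger.warning("product of rule %s failed sanitization; dropped", rule)
        return []
    out = []
    for frag in Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False):
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            logger.warning("fragment of rule %s failed sanitization; dropped", rule)
            continue
        if frag.GetNumAtoms() == 1 and frag.GetAtomWithIdx(0).GetSymbol() == "O":
            continue  # water leaving group
        out.append(Product(Chem.MolToSmiles(frag), site, rule))
    return out


def _add_oxygen(rw: Chem.RWMol, idx: int, double: bool) -> None:
    o = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(idx, o, Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE)


def _oxidize_snp(rw: Chem.RWMol, idx: int) -> None:
    a = rw.GetAtomWithIdx(idx)
    if a.GetSymbol() == "N":
        # charge-separated N-oxide keeps nitrogen at standard valence
        o = rw.AddAtom(Chem.Atom(8))
        rw.GetAtomWithIdx(o).SetFormalCharge(-1)
        a.SetFormalCharge(a.GetFormalCharge() + 1)
        rw.AddBond(idx, o, Chem.BondType.SINGLE)
    else:
        _add_oxygen(rw, idx, double=True)


def _hydroxylate(rw: Chem.RWMol, idx: int) -> bool:
    a = rw.GetAtomWithIdx(idx)
    if a.GetTotalNumHs() == 0:
        return False
    if a.GetNumExplicitHs() > 0:
        a.SetNumExplicitHs(a.GetNumExplicitHs() - 1)
    _add_oxygen(rw, idx, double=False)
    return True


def _carbonylate(rw: Chem.RWMol, idx: int) -> bool:
    """Oxidise a carbon to the corresponding carbonyl (needs >=2 H or one H
    plus an open valence after cleavage)."""
    a = rw.GetAtomWithIdx(idx)
    if a.GetSymbol() != "C":
        return False
    _add_oxygen(rw, idx, double=True)
    return True


def metabolize_atom_som(mol: Chem.Mol, atom_index: int) -> list[Product]:
    """Products of an atom SOM; empty list if no rule matches."""
    site = SiteKey.atom(atom_index)
    atom = mol.GetAtomWithIdx(atom_index)
    sym = atom.GetSymbol()

    if sym in _SNP:
        rw = Chem.RWMol(mol)
        _oxidize_snp(rw, atom_index)
        return _finalize(rw.GetMol(), site, f"{sym.lower()}_oxidation")

    if sym != "C":
        return []

    if atom.GetIsAromatic():
        if atom.GetTotalNumHs() == 0:
            return []
        rw = Chem.RWMol(mol)
        if not _hydroxylate(rw, atom_index):
            return []
        return _finalize(rw.GetMol(), site, "aromatic_hydroxylation")

    hetero = [
        n.GetIdx()
        for n in atom.GetNeighbors()
        if n.GetSymbol() in ("N", "O")
        and mol.GetBondBetweenAtoms(atom_index, n.GetIdx()).GetBondType()
        == Chem.BondType.SINGLE
    ]
    if not hetero:
        return []
    rw = Chem.RWMol(mol)
    for h_idx in hetero:
        rw.RemoveBond(atom_index, h_idx)
    probe = rw.GetMol()
    try:
        Chem.SanitizeMol(probe)
    except Exception:
        return []
    if len(Chem.GetMolFrags(probe)) < 2:
        return []  # still one piece: the cleavage did not split the molecule
    _carbonylate(rw, atom_index)
    return _finalize(rw.GetMol(), site, "dealkylation")


def metabolize_bond_som(mol: Chem.Mol, site: SiteKey) -> list[Product]:
    """Products of a bond or i-H pseudo-bond SOM; empty list if unmatched."""
    if site.kind == "hbond":
        return _metabolize_ch(mol, site)
    if site.kind != "bond":
        raise ValueError("metabolize_bond_som takes bond or hbond sites")
    i, j = site.a, site.b
    bond = mol.GetBondBetweenAtoms(i, j)
    if bond is None:
        return []
    si, sj = mol.GetAtomWithIdx(i).GetSymbol(), mol.GetAtomWithIdx(j).GetSymbol()

    if si == "C" and sj == "C" and bond.GetBondType() == Chem.BondType.DOUBLE:
        rw = Chem.RWMol(mol)
        rw.GetBondBetweenAtoms(i, j).SetBondType(Chem.BondType.SINGLE)
        o = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(i, o, Chem.BondType.SINGLE)
        rw.AddBond(j, o, Chem.BondType.SINGLE)
        return _finalize(rw.GetMol(), site, "epoxidation")

    if {si, sj} == {"C", "O"}:
        c_idx = i if si == "C" else j
        o_idx = j if si == "C" else i
        if bond.GetBondType() != Chem.BondType.SINGLE:
            return []
        if mol.GetAtomWithIdx(o_idx).GetDegree() == 1:
            # carbinol -> carbonyl
            if mol.GetAtomWithIdx(c_idx).GetTotalNumHs() == 0:
                return []
            rw = Chem.RWMol(mol)
            rw.GetBondBetweenAtoms(c_idx, o_idx).SetBondType(Chem.BondType.DOUBLE)
            return _finalize(rw.GetMol(), site, "alcohol_oxidation")
        return metabolize_atom_som(mol, c_idx)

    for x_idx, o_idx, x_sym in ((i, j, si), (j, i, sj)):
        if x_sym in _SNP and mol.GetAtomWithIdx(o_idx).GetSymbol() == "O":
            x = mol.GetAtomWithIdx(x_idx)
            o_nbrs = [n.GetIdx() for n in x.GetNeighbors() if n.GetSymbol() == "O"]
            if len(o_nbrs) > 1 and x_sym == "N":
                # several O on N: reduce all the way to the primary amine
                rw = Chem.RWMol(mol)
                # fix the nitrogen before removals so index shifts cannot bite
                n_atom = rw.GetAtomWithIdx(x_idx)
                n_atom.SetFormalCharge(0)
                n_atom.SetNoImplicit(False)
                for o_n in sorted(o_nbrs, reverse=True):
                    if rw.GetAtomWithIdx(o_n).GetDegree() == 1:
                        rw.RemoveAtom(o_n)
                return _finalize(rw.GetMol(), site, "nitro_reduction")
            # one O (or several on S/P): break this i-O bond
            rw = Chem.RWMol(mol)
            rw.RemoveBond(x_idx, o_idx)
            rw.GetAtomWithIdx(x_idx).SetFormalCharge(0)
            rw.GetAtomWithIdx(o_idx).SetFormalCharge(0)
            return _finalize(rw.GetMol(), site, "heteroatom_o_cleavage")
    return []


def _metabolize_ch(mol: Chem.Mol, site: SiteKey) -> list[Product]:
    idx = site.a
    atom = mol.GetAtomWithIdx(idx)
    if atom.GetSymbol() != "C" or atom.GetTotalNumHs() == 0:
        return []
    if any(n.GetSymbol() in ("N", "O") for n in atom.GetNeighbors()):
        prods = metabolize_atom_som(mol, idx)
        return [Product(p.smiles, site, p.rule) for p in prods]
    rw = Chem.RWMol(mol)
    if not _hydroxylate(rw, idx):
        return []
    return _finalize(rw.GetMol(), site, "ch_hydroxylation")


def _ring_interconversion(mol: Chem.Mol, ring_bonds: Sequence[int]) -> list[Product]:
    """Aromatic ring -> saturated carbocycle, or saturated ring -> aromatic.

    The product's hydrogen counts follow from standard valence after the
    bond-order change; products are flagged with the ring rule name.
    """
    bonds = [mol.GetBondWithIdx(b) for b in ring_bonds]
    ring_atoms = sorted({a for b in bonds for a in (b.GetBeginAtomIdx(), b.GetEndAtomIdx())})
    site = SiteKey.bond(*sorted((bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx())))
    rw = Chem.RWMol(mol)
    if all(b.GetIsAromatic() for b in bonds):
        for b in bonds:
            rb = rw.GetBondBetweenAtoms(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
            rb.SetBondType(Chem.BondType.SINGLE)
            rb.SetIsAromatic(False)
        for a in ring_atoms:
            rw.GetAtomWithIdx(a).SetIsAromatic(False)
        return _finalize(rw.GetMol(), site, "ring_interconversion")
    # try to aromatise an even-sized saturated ring
    if len(ring_atoms) % 2 or any(
        rw.GetAtomWithIdx(a).GetSymbol() not in ("C", "N", "O", "S")
        for a in ring_atoms
    ):
        return []
    order = _ring_order(mol, ring_bonds, ring_atoms)
    if order is None:
        return []
    for k in range(len(order)):
        a, b = order[k], order[(k + 1) % len(order)]
        rb = rw.GetBondBetweenAtoms(a, b)
        rb.SetBondType(Chem.BondType.DOUBLE if k % 2 == 0 else Chem.BondType.SINGLE)
    return _finalize(rw.GetMol(), site, "ring_interconversion")


def _ring_order(mol, ring_bonds, ring_atoms):
    adj = {a: [] for a in ring_atoms}
    for bi in ring_bonds:
        b = mol.GetBondWithIdx(bi)
        adj[b.GetBeginAtomIdx()].append(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].append(b.GetBeginAtomIdx())
    start = ring_atoms[0]
    order = [start]
    prev = None
    while len(order) < len(ring_atoms):
        nxt = [n for n in adj[order[-1]] if n != prev]
        if not nxt:
            return None
        prev = order[-1]
        order.append(nxt[0])
    return order


def generate_metabolites(
    mol: Chem.Mol,
    called: Iterable[SiteKey],
    parent_id: str = "mol",
) -> MetaboliteSet:
    """Union of products over all called sites, deduplicated canonically."""
    called = list(called)
    result = MetaboliteSet(parent_id)
    seen: set[str] = set()

    def _take(prods: list[Product]) -> None:
        for p in prods:
            if p.smiles not in seen:
                seen.add(p.smiles)
                result.products.append(p)

    for site in called:
        if site.kind == "atom":
            _take(metabolize_atom_som(mol, site.a))
        else:
            _take(metabolize_bond_som(mol, site))

    called_bonds = {s for s in called if s.kind == "bond"}
    for ring in mol.GetRingInfo().BondRings():
        keys = {
            SiteKey.bond(
                mol.GetBondWithIdx(b).GetBeginAtomIdx(),
                mol.GetBondWithIdx(b).GetEndAtomIdx(),
            )
            for b in ring
        }
        if keys and keys <= called_bonds:
            _take(_ring_interconversion(mol, list(ring)))
    return result


def metabolites_frame(sets: Iterable[MetaboliteSet]):
    """Flatten metabolite sets to a table: parent_id, rule, site, product."""
    import pandas as pd

    rows = [
        {
            "parent_id": ms.parent_id,
            "rule": p.rule,
            "site": f"{p.site.kind}:{'-'.join(str(a) for a in p.site.atoms())}",
            "product_smiles": p.smiles,
        }
        for ms in sets
        for p in ms.products
    ]
    return pd.DataFrame(rows, columns=["parent_id", "rule", "site", "product_smiles"])
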