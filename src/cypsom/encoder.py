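"""Directed message-passing encoder, probability head and weighted loss.

Hidden states live on *directed* bonds.  For a bond v-w the two directed
states h_vw and h_wv are initialised from the start atom's descriptors spliced
with the (orientation-free) bond descriptors,

    h0_vw = tau(W_a [x_v, e_vw]),

and updated for ``depth`` rounds by aggregating the incoming directed states
while excluding the reverse bond — the exclusion is what prevents two-hop
message loops:

    m_vw^{t+1} = sum_{k in N(v), k != w} h_kv^t
    h_vw^{t+1} = drop(tau(h0_vw + W_m m_vw^{t+1})).

Readout produces one embedding per candidate site.  Bonds average their two
directions, atoms splice their own descriptors with the sum of outgoing
states:

    F_vw = BN((h_vw^n + h_wv^n) / 2)
    F_v  = BN(drop(tau(W_o [x_v, sum_w h_vw^n])))

with one *shared* batch-normalization layer for atoms and bonds, so both site
kinds land in the same embedding space and a single discriminator can score
them.  The i-H pseudo-bond sites of hydrogen-bearing heavy atoms are realised
as bonds to per-atom pseudo hydrogen vertices carrying a fixed H encoding;
they flow through the identical message-passing machinery.

A single linear layer + softmax turns a site embedding into (p_positive,
p_negative); the training loss weights positive and negative sites separately,

    loss = a * loss_p + b * loss_n,

with loss_p / loss_n the cross-entropy summed over truly positive / negative
sites — the knob that keeps recall alive on heavily negative-dominated site
data.

Everything here is NumPy with explicit reverse-mode gradients and an Adam
optimizer; float64 throughout, so eval-mode forward passes are bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from . import featurize
from .chem import MoleculeRecord, SiteKey, candidate_sites
from .errors import ConfigError

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

@dataclass
class MolGraph:
    """A featurized molecular graph augmented with pseudo hydrogen vertices.

    Vertices 0..n_heavy-1 are the heavy atoms; the remaining vertices are one
    pseudo-H per hydrogen-bearing heavy atom.  Undirected bond b owns the
    directed edge pair (2b, 2b+1); the first ``n_real_bonds`` undirected
    bonds are chemical bonds, the rest are i-H pseudo-bonds.
    """

    mol_id: str
    n_nodes: int
    n_heavy: int
    node_feats: np.ndarray          # (n_nodes, ATOM_FDIM)
    ubond_feats: np.ndarray         # (n_ubonds, BOND_FDIM)
    ubond_atoms: np.ndarray         # (n_ubonds, 2) vertex indices
    n_real_bonds: int
    edge_src: np.ndarray            # (2*n_ubonds,)
    edge_dst: np.ndarray            # (2*n_ubonds,)
    sites: list[SiteKey] = field(default_factory=list)

    @property
    def n_ubonds(self) -> int:
        return len(self.ubond_feats)

    @property
    def n_edges(self) -> int:
        return 2 * self.n_ubonds

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def build_graph(record: MoleculeRecord) -> MolGraph:
    """Featurize one molecule into a :class:`MolGraph`.

    Site order matches :func:`cypsom.chem.candidate_sites`: heavy atoms,
    chemical bonds, i-H pseudo-bonds.
    """
    mol = record.mol
    n_heavy = mol.GetNumAtoms()
    node_rows = [featurize.atom_features(mol, i) for i in range(n_heavy)]
    h_enc = featurize.hydrogen_features()

    ubond_feats: list[np.ndarray] = []
    ubond_atoms: list[tuple[int, int]] = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        ubond_feats.append(featurize.bond_features(mol, i, j))
        ubond_atoms.append((i, j))
    n_real = len(ubond_atoms)

    hb_enc = featurize.hbond_features()
    for a in mol.GetAtoms():
        if a.GetTotalNumHs() > 0:
            pseudo = len(node_rows)
            node_rows.append(h_enc)
            ubond_feats.append(hb_enc)
            ubond_atoms.append((a.GetIdx(), pseudo))

    n_ub = len(ubond_atoms)
    src = np.empty(2 * n_ub, dtype=np.int64)
    dst = np.empty(2 * n_ub, dtype=np.int64)
    for b, (i, j) in enumerate(ubond_atoms):
        src[2 * b], dst[2 * b] = i, j
        src[2 * b + 1], dst[2 * b + 1] = j, i

    return MolGraph(
        mol_id=record.mol_id,
        n_nodes=len(node_rows),
        n_heavy=n_heavy,
        node_feats=np.vstack(node_rows) if node_rows else np.zeros((0, featurize.ATOM_FDIM)),
        ubond_feats=np.vstack(ubond_feats) if ubond_feats else np.zeros((0, featurize.BOND_FDIM)),
        ubond_atoms=np.asarray(ubond_atoms, dtype=np.int64).reshape(n_ub, 2),
        n_real_bonds=n_real,
        edge_src=src,
        edge_dst=dst,
        sites=candidate_sites(mol),
    )


@dataclass
class BatchedGraph:
    """Disjoint union of molecular graphs with index offsets applied."""

    node_feats: np.ndarray
    ubond_feats: np.ndarray
    ubond_atoms: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    n_nodes: int
    heavy_index: np.ndarray        # global vertex index of every heavy atom
    site_rows: np.ndarray          # per site: row selector, see stack order
    site_is_atom: np.ndarray       # bool per site
    site_mol: np.ndarray           # molecule index per site
    node_mol: np.ndarray           # molecule index per vertex
    sites: list[SiteKey]
    mol_ids: list[str]
    n_mols: int

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    @property
    def n_ubonds(self) -> int:
        return len(self.ubond_feats)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def batch_graphs(graphs: Sequence[MolGraph]) -> BatchedGraph:
    """Concatenate graphs into one big graph.

    Site embeddings are later stacked as [all heavy-atom rows; all undirected
    bond rows]; ``site_rows`` maps each candidate site of each molecule (in
    per-molecule order: atoms, bonds, hbonds) into that stack.
    """
    node_feats, ubond_feats, ubond_atoms = [], [], []
    srcs, dsts = [], []
    heavy_index, node_mol = [], []
    site_rows, site_is_atom, site_mol = [], [], []
    sites: list[SiteKey] = []
    mol_ids: list[str] = []
    node_off = 0
    ubond_off = 0
    n_heavy_total = sum(g.n_heavy for g in graphs)
    heavy_off = 0

    for mi, g in enumerate(graphs):
        node_feats.append(g.node_feats)
        ubond_feats.append(g.ubond_feats)
        ubond_atoms.append(g.ubond_atoms + node_off)
        srcs.append(g.edge_src + node_off)
        dsts.append(g.edge_dst + node_off)
        heavy_index.extend(range(node_off, node_off + g.n_heavy))
        node_mol.extend([mi] * g.n_nodes)
        mol_ids.append(g.mol_id)

        # per-molecule site order: atoms, real bonds, hbond pseudo-bonds
        for i in range(g.n_heavy):
            site_rows.append(heavy_off + i)
            site_is_atom.append(True)
            site_mol.append(mi)
        for b in range(g.n_ubonds):
            site_rows.append(n_heavy_total + ubond_off + b)
            site_is_atom.append(False)
            site_mol.append(mi)
        sites.extend(g.sites)

        node_off += g.n_nodes
        ubond_off += g.n_ubonds
        heavy_off += g.n_heavy

    return BatchedGraph(
        node_feats=np.vstack(node_feats),
        ubond_feats=np.vstack(ubond_feats) if ubond_off else np.zeros((0, featurize.BOND_FDIM)),
        ubond_atoms=np.vstack(ubond_atoms) if ubond_off else np.zeros((0, 2), dtype=np.int64),
        edge_src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64),
        edge_dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64),
        n_nodes=node_off,
        heavy_index=np.asarray(heavy_index, dtype=np.int64),
        site_rows=np.asarray(site_rows, dtype=np.int64),
        site_is_atom=np.asarray(site_is_atom, dtype=bool),
        site_mol=np.asarray(site_mol, dtype=np.int64),
        node_mol=np.asarray(node_mol, dtype=np.int64),
        sites=sites,
        mol_ids=mol_ids,
        n_mols=len(graphs),
    )


def _rev(n_edges: int) -> np.ndarray:
    """Reverse-edge permutation for pair-ordered directed edges."""
    r = np.arange(n_edges)
    r[0::2] += 1
    r[1::2] -= 1
    return r


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class EncoderParams:
    """Learned matrices and normalization state of one directed-MPNN encoder.

    ``W_a`` maps the spliced [x_v, e_vw] input (width h_a) to the hidden
    width h; ``W_m`` mixes aggregated messages; ``W_o`` maps the spliced
    [x_v, sum of outgoing states] (width h_b) to the atom embedding.
    """

    W_a: np.ndarray
    W_m: np.ndarray
    W_o: np.ndarray
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray
    depth: int
    dropout: float
    activation: str = "leaky_relu"
    leaky_slope: float = 0.01

    @property
    def hidden_size(self) -> int:
        return self.W_a.shape[0]

    def trainable(self) -> dict[str, np.ndarray]:
        return {
            "W_a": self.W_a, "W_m": self.W_m, "W_o": self.W_o,
            "bn_gamma": self.bn_gamma, "bn_beta": self.bn_beta,
        }


def init_encoder_params(
    hidden_size: int = 300,
    depth: int = 3,
    dropout: float = 0.05,
    activation: str = "leaky_relu",
    leaky_slope: float = 0.01,
    rng: np.random.Generator | None = None,
) -> EncoderParams:
    if hidden_size < 1 or depth < 0:
        raise ConfigError("hidden_size must be >=1 and depth >=0")
    if not 0.0 <= dropout < 1.0:
        raise ConfigError("dropout must be in [0,1)")
    if activation not in ("leaky_relu", "relu"):
        raise ConfigError(f"unknown activation {activation!r}")
    rng = rng or np.random.default_rng()
    h_a = featurize.ATOM_FDIM + featurize.BOND_FDIM
    h_b = featurize.ATOM_FDIM + hidden_size

    def he(shape):
        return rng.standard_normal(shape) * np.sqrt(2.0 / shape[1])

    return EncoderParams(
        W_a=he((hidden_size, h_a)),
        W_m=he((hidden_size, hidden_size)),
        W_o=he((hidden_size, h_b)),
        bn_gamma=np.ones(hidden_size),
        bn_beta=np.zeros(hidden_size),
        bn_mean=np.zeros(hidden_size),
        bn_var=np.ones(hidden_size),
        depth=depth,
        dropout=dropout,
        activation=activation,
        leaky_slope=leaky_slope,
    )


def _act(z: np.ndarray, params: EncoderParams) -> np.ndarray:
    slope = params.leaky_slope if params.activation == "leaky_relu" else 0.0
    return np.where(z > 0, z, slope * z)


def _act_grad(z: np.ndarray, params: EncoderParams) -> np.ndarray:
    slope = params.leaky_slope if params.activation == "leaky_relu" else 0.0
    return np.where(z > 0, 1.0, slope)


# ---------------------------------------------------------------------------
# Forward operations
# ---------------------------------------------------------------------------

def init_messages(graph: BatchedGraph, params: EncoderParams):
    """Initial directed-bond states h0_vw = tau(W_a [x_v, e_vw]).

    Returns (h0, cache) where h0 has one row per directed edge.
    """
    feat_in = np.hstack(
        [graph.node_feats[graph.edge_src], graph.ubond_feats[np.arange(graph.n_edges) // 2]]
    ) if graph.n_edges else np.zeros((0, params.W_a.shape[1]))
    if feat_in.shape[1] != params.W_a.shape[1]:
        raise ConfigError(
            f"W_a expects input width {params.W_a.shape[1]}, got {feat_in.shape[1]}"
        )
    z0 = feat_in @ params.W_a.T
    return _act(z0, params), (feat_in, z0)


def message_pass(
    h: np.ndarray,
    h0: np.ndarray,
    graph: BatchedGraph,
    params: EncoderParams,
    dropout_mask: np.ndarray | None = None,
):
    """One message-passing round: aggregate incoming states excluding the
    reverse bond, mix through W_m, add the initial state, activate, drop.

    Returns (h_next, cache).
    """
    rev = _rev(graph.n_edges)
    s = np.zeros((graph.n_nodes, params.hidden_size))
    np.add.at(s, graph.edge_dst, h)
    m = s[graph.edge_src] - h[rev]
    z = h0 + m @ params.W_m.T
    out = _act(z, params)
    if dropout_mask is not None:
        out = out * dropout_mask
    return out, (m, z)


def readout_bond(h_n: np.ndarray, graph: BatchedGraph) -> np.ndarray:
    """Pre-normalization bond embeddings: mean of the two directions."""
    return 0.5 * (h_n[0::2] + h_n[1::2])


def readout_atom(
    h_n: np.ndarray,
    graph: BatchedGraph,
    params: EncoderParams,
    dropout_mask: np.ndarray | None = None,
):
    """Pre-normalization atom embeddings tau(W_o [x_v, sum_w h_vw^n]).

    Computed for every vertex (pseudo-H rows are discarded by the caller).
    Returns (a_out, cache).
    """
    s_out = np.zeros((graph.n_nodes, params.hidden_size))
    np.add.at(s_out, graph.edge_src, h_n)
    g_in = np.hstack([graph.node_feats, s_out])
    z_o = g_in @ params.W_o.T
    a_out = _act(z_o, params)
    if dropout_mask is not None:
        a_out = a_out * dropout_mask
    return a_out, (g_in, z_o)


def batch_norm_forward(
    x: np.ndarray, params: EncoderParams, training: bool
):
    """Shared batch normalization over stacked atom+bond site rows."""
    if training:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        params.bn_mean[:] = (1 - _BN_MOMENTUM) * params.bn_mean + _BN_MOMENTUM * mu
        n = max(x.shape[0], 2)
        params.bn_var[:] = (1 - _BN_MOMENTUM) * params.bn_var + _BN_MOMENTUM * var * n / (n - 1)
    else:
        mu, var = params.bn_mean, params.bn_var
    std = np.sqrt(var + _BN_EPS)
    xhat = (x - mu) / std
    return params.bn_gamma * xhat + params.bn_beta, (xhat, std)


def _batch_norm_backward(dout, cache, params):
    xhat, std = cache
    n = xhat.shape[0]
    dgamma = (dout * xhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dxhat = dout * params.bn_gamma
    dx = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
    return dx, dgamma, dbeta


def encode_sites(
    graph: BatchedGraph,
    params: EncoderParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Full site-encoder forward pass.

    Returns (F, cache): F has one row per candidate site (batch site order),
    after shared batch normalization.
    """
    h0, c_init = init_messages(graph, params)
    h = h0
    masks, pass_caches, hs = [], [], [h0]
    keep = 1.0 - params.dropout
    for _ in range(params.depth):
        mask = None
        if training and params.dropout > 0:
            if rng is None:
                raise ConfigError("training with dropout requires an rng")
            mask = (rng.random(h.shape) < keep) / keep
        h, c = message_pass(h, h0, graph, params, mask)
        masks.append(mask)
        pass_caches.append(c)
        hs.append(h)

    bond_pre = readout_bond(h, graph)
    a_mask = None
    if training and params.dropout > 0:
        a_mask = (rng.random((graph.n_nodes, params.hidden_size)) < keep) / keep
    atom_all, c_atom = readout_atom(h, graph, params, a_mask)
    atom_pre = atom_all[graph.heavy_index]

    stacked = np.vstack([atom_pre, bond_pre])
    normed, c_bn = batch_norm_forward(stacked, params, training)
    F = normed[graph.site_rows]
    cache = {
        "c_init": c_init, "pass_caches": pass_caches, "masks": masks,
        "hs": hs, "a_mask": a_mask, "c_atom": c_atom, "c_bn": c_bn,
        "n_heavy_total": len(graph.heavy_index),
    }
    return F, cache


def encode_sites_backward(
    dF: np.ndarray, graph: BatchedGraph, params: EncoderParams, cache
) -> dict[str, np.ndarray]:
    """Reverse-mode gradients of :func:`encode_sites` w.r.t. the trainable
    parameters, given dLoss/dF."""
    n_heavy = cache["n_heavy_total"]
    n_stack = n_heavy + graph.n_ubonds
    dstacked_post = np.zeros((n_stack, params.hidden_size))
    np.add.at(dstacked_post, graph.site_rows, dF)

    dstacked, dgamma, dbeta = _batch_norm_backward(dstacked_post, cache["c_bn"], params)
    datom_pre = dstacked[:n_heavy]
    dbond_pre = dstacked[n_heavy:]

    # atom readout branch
    datom_all = np.zeros((graph.n_nodes, params.hidden_size))
    datom_all[graph.heavy_index] = datom_pre
    if cache["a_mask"] is not None:
        datom_all = datom_all * cache["a_mask"]
    g_in, z_o = cache["c_atom"]
    dz_o = datom_all * _act_grad(z_o, params)
    dW_o = dz_o.T @ g_in
    dg = dz_o @ params.W_o
    ds_out = dg[:, featurize.ATOM_FDIM:]

    # gradients flowing into the final directed-bond states
    dh = ds_out[graph.edge_src]
    dh[0::2] += 0.5 * dbond_pre
    dh[1::2] += 0.5 * dbond_pre

    rev = _rev(graph.n_edges)
    dW_m = np.zeros_like(params.W_m)
    dh0 = np.zeros_like(dh)
    for t in range(params.depth - 1, -1, -1):
        mask = cache["masks"][t]
        if mask is not None:
            dh = dh * mask
        m, z = cache["pass_caches"][t]
        dz = dh * _act_grad(z, params)
        dh0 += dz
        dW_m += dz.T @ m
        dm = dz @ params.W_m
        tsum = np.zeros((graph.n_nodes, params.hidden_size))
        np.add.at(tsum, graph.edge_src, dm)
        dh = tsum[graph.edge_dst] - dm[rev]
    dh0 += dh  # h0 is also h at t=0

    feat_in, z0 = cache["c_init"]
    dz0 = dh0 * _act_grad(z0, params)
    dW_a = dz0.T @ feat_in
    return {"W_a": dW_a, "W_m": dW_m, "W_o": dW_o, "bn_gamma": dgamma, "bn_beta": dbeta}


# ---------------------------------------------------------------------------
# Molecule encoder
# ---------------------------------------------------------------------------

@dataclass
class MoleculeEncoderParams:
    """Second, independent directed-MPNN that summarises the whole molecular
    skeleton into one vector (sum-pooled atom outputs through a linear map)."""

    core: EncoderParams
    W_pool: np.ndarray              # (out_dim, hidden)
    pooling: str = "sum"

    @property
    def out_dim(self) -> int:
        return self.W_pool.shape[0]

    def trainable(self) -> dict[str, np.ndarray]:
        d = {f"core.{k}": v for k, v in self.core.trainable().items()}
        d["W_pool"] = self.W_pool
        return d


def init_molecule_encoder_params(
    hidden_size: int = 64,
    depth: int = 2,
    out_dim: int = 32,
    dropout: float = 0.0,
    activation: str = "leaky_relu",
    pooling: str = "sum",
    rng: np.random.Generator | None = None,
) -> MoleculeEncoderParams:
    if pooling not in ("sum", "mean"):
        raise ConfigError(f"unknown pooling {pooling!r}")
    rng = rng or np.random.default_rng()
    core = init_encoder_params(hidden_size, depth, dropout, activation, rng=rng)
    W_pool = rng.standard_normal((out_dim, hidden_size)) * np.sqrt(2.0 / hidden_size)
    return MoleculeEncoderParams(core=core, W_pool=W_pool, pooling=pooling)


def molecule_embedding(
    graph: BatchedGraph,
    params: MoleculeEncoderParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """One embedding vector per molecule in the batch.

    Runs the second encoder's message passing, takes the heavy-atom outputs,
    pools them per molecule (sum or mean) and applies a learned linear map.
    Returns (molvecs, cache), molvecs of shape (n_mols, out_dim).
    """
    core = params.core
    h0, c_init = init_messages(graph, core)
    h = h0
    masks, pass_caches = [], []
    keep = 1.0 - core.dropout
    for _ in range(core.depth):
        mask = None
        if training and core.dropout > 0:
            mask = (rng.random(h.shape) < keep) / keep
        h, c = message_pass(h, h0, graph, core, mask)
        masks.append(mask)
        pass_caches.append(c)
    atom_all, c_atom = readout_atom(h, graph, core, None)
    atom_out = atom_all[graph.heavy_index]
    heavy_mol = graph.node_mol[graph.heavy_index]
    pooled = np.zeros((graph.n_mols, core.hidden_size))
    np.add.at(pooled, heavy_mol, atom_out)
    if params.pooling == "mean":
        counts = np.bincount(heavy_mol, minlength=graph.n_mols).astype(float)
        pooled = pooled / np.maximum(counts, 1.0)[:, None]
    molvecs = pooled @ params.W_pool.T
    cache = {
        "c_init": c_init, "pass_caches": pass_caches, "masks": masks,
        "c_atom": c_atom, "pooled": pooled, "heavy_mol": heavy_mol,
    }
    return molvecs, cache


def molecule_embedding_backward(
    dmol: np.ndarray, graph: BatchedGraph, params: MoleculeEncoderParams, cache
) -> dict[str, np.ndarray]:
    """Gradients of :func:`molecule_embedding` w.r.t. its parameters."""
    core = params.core
    dW_pool = dmol.T @ cache["pooled"]
    dpooled = dmol @ params.W_pool
    heavy_mol = cache["heavy_mol"]
    datom_out = dpooled[heavy_mol]
    if params.pooling == "mean":
        counts = np.bincount(heavy_mol, minlength=graph.n_mols).astype(float)
        datom_out = datom_out / np.maximum(counts, 1.0)[heavy_mol][:, None]
    datom_all = np.zeros((graph.n_nodes, core.hidden_size))
    datom_all[graph.heavy_index] = datom_out

    g_in, z_o = cache["c_atom"]
    dz_o = datom_all * _act_grad(z_o, core)
    dW_o = dz_o.T @ g_in
    ds_out = (dz_o @ core.W_o)[:, featurize.ATOM_FDIM:]
    dh = ds_out[graph.edge_src]

    rev = _rev(graph.n_edges)
    dW_m = np.zeros_like(core.W_m)
    dh0 = np.zeros_like(dh)
    for t in range(core.depth - 1, -1, -1):
        mask = cache["masks"][t]
        if mask is not None:
            dh = dh * mask
        m, z = cache["pass_caches"][t]
        dz = dh * _act_grad(z, core)
        dh0 += dz
        dW_m += dz.T @ m
        dm = dz @ core.W_m
        tsum = np.zeros((graph.n_nodes, core.hidden_size))
        np.add.at(tsum, graph.edge_src, dm)
        dh = tsum[graph.edge_dst] - dm[rev]
    dh0 += dh
    feat_in, z0 = cache["c_init"]
    dz0 = dh0 * _act_grad(z0, core)
    dW_a = dz0.T @ feat_in
    return {
        "core.W_a": dW_a, "core.W_m": dW_m, "core.W_o": dW_o,
        "core.bn_gamma": np.zeros_like(core.bn_gamma),
        "core.bn_beta": np.zeros_like(core.bn_beta),
        "W_pool": dW_pool,
    }


# ---------------------------------------------------------------------------
# Probability head and loss
# ---------------------------------------------------------------------------

@dataclass
class HeadParams:
    """Single linear layer mapping a site embedding to two logits."""

    W: np.ndarray                   # (2, in_dim)
    b: np.ndarray                   # (2,)

    def trainable(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}


def init_head_params(in_dim: int, rng: np.random.Generator | None = None) -> HeadParams:
    rng = rng or np.random.default_rng()
    return HeadParams(W=rng.standard_normal((2, in_dim)) * np.sqrt(1.0 / in_dim),
                      b=np.zeros(2))


def probability_head(F: np.ndarray, params: HeadParams) -> np.ndarray:
    """Per-site (p_positive, p_negative) via softmax over two logits.

    Rows sum to one; column 0 is the positive probability.
    """
    logits = F @ params.W.T + params.b
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class LossWeights:
    """Importance of positive-site (a) and negative-site (b) cross-entropy."""

    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or (self.a == 0 and self.b == 0):
            raise ConfigError("loss weights must be non-negative, not both zero")


def weighted_loss(
    probs: np.ndarray, y: np.ndarray, weights: LossWeights = LossWeights()
) -> float:
    """loss = a * loss_p + b * loss_n with cross-entropy summed over truly
    positive / truly negative sites.  With a = b = 1 this is plain summed
    cross-entropy."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty batch")
    p_true = np.where(y == 1, probs[:, 0], probs[:, 1])
    ce = -np.log(np.clip(p_true, 1e-300, None))
    return float(weights.a * ce[y == 1].sum() + weights.b * ce[y == 0].sum())


def weighted_loss_grad(
    probs: np.ndarray, y: np.ndarray, weights: LossWeights
) -> np.ndarray:
    """dLoss/dlogits for the softmax + weighted cross-entropy head."""
    y = np.asarray(y)
    onehot = np.stack([y == 1, y == 0], axis=1).astype(float)
    w = np.where(y == 1, weights.a, weights.b)[:, None]
    return (probs - onehot) * w


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
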