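"""Directed message passing: oracle equivalence, loop avoidance,
equivariance, head and loss semantics.

The oracle is a deliberately naive per-bond dictionary implementation of the
encoder equations, kept independent of the vectorized code path.
"""

import numpy as np
import pytest
from rdkit import Chem

from cypsom import encoder as enc, featurize as ft
from cypsom.chem import record_from_smiles

_BN_EPS = 1e-5


# ---------------------------------------------------------------------------
# Naive oracle
# ---------------------------------------------------------------------------

def _act(z, params):
    slope = params.leaky_slope if params.activation == "leaky_relu" else 0.0
    return np.where(z > 0, z, slope * z)


def oracle_site_embeddings(graph: enc.MolGraph, params: enc.EncoderParams):
    """Straight-line recomputation of the encoder on one molecule:
    dictionaries keyed by directed bond, explicit neighbour loops, shared
    eval-mode normalization."""
    edges = []
    for b in range(graph.n_ubonds):
        i, j = graph.ubond_atoms[b]
        edges.append((i, j, b))
        edges.append((j, i, b))

    h0 = {}
    for (u, v, b) in edges:
        x = np.concatenate([graph.node_feats[u], graph.ubond_feats[b]])
        h0[(u, v, b)] = _act(params.W_a @ x, params)
    h = dict(h0)
    for _ in range(params.depth):
        new = {}
        for (u, v, b) in edges:
            m = np.zeros(params.hidden_size)
            for (k, w, b2) in edges:
                # incoming edges k->u, excluding the reverse of (u,v,b)
                if w == u and not (k == v and b2 == b):
                    m += h[(k, w, b2)]
            new[(u, v, b)] = _act(h0[(u, v, b)] + params.W_m @ m, params)
        h = new

    bond_pre = np.array(
        [(h[(i, j, b)] + h[(j, i, b)]) / 2 for b, (i, j) in enumerate(graph.ubond_atoms)]
    )
    atom_pre = []
    for v in range(graph.n_heavy):
        s = np.zeros(params.hidden_size)
        for (u, w, b) in edges:
            if u == v:
                s += h[(u, w, b)]
        g = np.concatenate([graph.node_feats[v], s])
        atom_pre.append(_act(params.W_o @ g, params))
    stacked = np.vstack([np.array(atom_pre), bond_pre]) if len(bond_pre) else np.array(atom_pre)
    normed = (
        params.bn_gamma * (stacked - params.bn_mean) / np.sqrt(params.bn_var + _BN_EPS)
        + params.bn_beta
    )
    return normed  # rows: heavy atoms, then undirected bonds (site order)


SMALL_MOLECULES = ["CCO", "CC(C)=O", "c1ccoc1", "CS(=O)C", "NCC#N", "OCC(O)CO"]


@pytest.mark.parametrize("depth", [1, 2, 3])
@pytest.mark.parametrize("smiles", SMALL_MOLECULES)
def test_vectorized_encoder_matches_naive_oracle(smiles, depth):
    """The batched encoder equals the per-bond loop recomputation on small
    molecules at every depth."""
    rec = record_from_smiles(smiles, "m")
    assert rec.mol.GetNumAtoms() <= 6
    graph = enc.build_graph(rec)
    rng = np.random.default_rng(depth)
    params = enc.init_encoder_params(hidden_size=9, depth=depth, dropout=0.0, rng=rng)
    params.bn_mean = rng.standard_normal(9) * 0.1
    params.bn_var = 1.0 + rng.random(9)
    F, _ = enc.encode_sites(enc.batch_graphs([graph]), params, training=False)
    expected = oracle_site_embeddings(graph, params)
    np.testing.assert_allclose(F, expected, atol=1e-6)


def _tiny_batch(node_feats, ubond_atoms, ubond_feats):
    """Hand-built batched graph for closed-form examples."""
    graphs = enc.MolGraph(
        mol_id="t",
        n_nodes=len(node_feats),
        n_heavy=len(node_feats),
        node_feats=np.asarray(node_feats, dtype=float),
        ubond_feats=np.asarray(ubond_feats, dtype=float),
        ubond_atoms=np.asarray(ubond_atoms, dtype=np.int64).reshape(-1, 2),
        n_real_bonds=len(ubond_atoms),
        edge_src=np.array([a for i, j in ubond_atoms for a in (i, j)], dtype=np.int64),
        edge_dst=np.array([a for i, j in ubond_atoms for a in (j, i)], dtype=np.int64),
        sites=[],
    )
    return enc.batch_graphs([graphs])


def _params(W_a=None, W_m=None, W_o=None, h=3, depth=1, activation="relu"):
    p = enc.init_encoder_params(h, depth, 0.0, activation, rng=np.random.default_rng(0))
    if W_a is not None:
        p.W_a = np.asarray(W_a, dtype=float)
    if W_m is not None:
        p.W_m = np.asarray(W_m, dtype=float)
    if W_o is not None:
        p.W_o = np.asarray(W_o, dtype=float)
    return p


class TestInitMessages:
    def test_identity_weights_concatenate_features(self):
        batch = _tiny_batch([[1, 0], [0, 1]], [(0, 1)], [[1]])
        p = _params(W_a=np.eye(3))
        h0, _ = enc.init_messages(batch, p)
        np.testing.assert_array_equal(h0[0], [1, 0, 1])  # [x_v, e_vw]

    def test_negated_weights_are_clamped_by_relu(self):
        batch = _tiny_batch([[1, 0], [0, 1]], [(0, 1)], [[1]])
        p = _params(W_a=-np.eye(3))
        h0, _ = enc.init_messages(batch, p)
        np.testing.assert_array_equal(h0[0], [0, 0, 0])

    def test_shape_mismatch_is_config_error(self):
        from cypsom.errors import ConfigError

        batch = _tiny_batch([[1, 0], [0, 1]], [(0, 1)], [[1]])
        with pytest.raises(ConfigError):
            enc.init_messages(batch, _params(W_a=np.eye(4)))


class TestMessagePass:
    def test_reverse_bond_excluded_on_path(self):
        """On A-B-C the message into B->C is exactly h_{A->B}."""
        batch = _tiny_batch(
            [[1, 0], [0, 1], [1, 1]], [(0, 1), (1, 2)], [[1], [1]]
        )
        p = _params(W_a=np.eye(3))
        h0, _ = enc.init_messages(batch, p)
        _, (m, _) = enc.message_pass(h0, h0, batch, p)
        # edge order: 0:A->B, 1:B->A, 2:B->C, 3:C->B
        np.testing.assert_array_equal(m[2], h0[0])
        np.testing.assert_array_equal(m[0], np.zeros(3))

    def test_isolated_diatomic_has_zero_message(self):
        batch = _tiny_batch([[1, 0], [0, 1]], [(0, 1)], [[1]])
        p = _params(W_a=np.eye(3))
        h0, _ = enc.init_messages(batch, p)
        _, (m, _) = enc.message_pass(h0, h0, batch, p)
        assert not m.any()

    def test_perturbing_reverse_state_never_leaks(self):
        """Loop avoidance: changing h_wv leaves m_vw untouched (to float
        rounding; the vectorized path subtracts the reverse state from the
        full incoming sum)."""
        rec = record_from_smiles("CC(C)C(N)=O", "m")
        batch = enc.batch_graphs([enc.build_graph(rec)])
        p = enc.init_encoder_params(8, 2, 0.0, rng=np.random.default_rng(5))
        h0, _ = enc.init_messages(batch, p)
        _, (m_ref, _) = enc.message_pass(h0, h0, batch, p)
        for d in range(0, batch.n_edges, 3):
            rev = d + 1 if d % 2 == 0 else d - 1
            h_pert = h0.copy()
            h_pert[rev] += 100.0
            _, (m_pert, _) = enc.message_pass(h_pert, h0, batch, p)
            np.testing.assert_allclose(m_pert[d], m_ref[d], atol=1e-9)


class TestReadout:
    def test_bond_readout_is_mean_of_directions(self):
        batch = _tiny_batch([[1, 0], [0, 1]], [(0, 1)], [[1]])
        h_n = np.array([[2.0], [4.0]])
        np.testing.assert_array_equal(enc.readout_bond(h_n, batch), [[3.0]])

    def test_bond_readout_is_orientation_symmetric(self):
        rec = record_from_smiles("c1ccccc1O", "m")
        batch = enc.batch_graphs([enc.build_graph(rec)])
        p = enc.init_encoder_params(6, 2, 0.0, rng=np.random.default_rng(2))
        F, _ = enc.encode_sites(batch, p, training=False)
        # symmetric by construction: recompute with swapped directed states
        h0, _ = enc.init_messages(batch, p)
        h = h0
        for _ in range(p.depth):
            h, _ = enc.message_pass(h, h0, batch, p)
        swapped = h.copy()
        swapped[0::2], swapped[1::2] = h[1::2], h[0::2]
        np.testing.assert_allclose(
            enc.readout_bond(h, batch), enc.readout_bond(swapped, batch)
        )

    def test_symmetric_atoms_get_identical_embeddings(self):
        rec = record_from_smiles("c1ccccc1", "benzene")
        batch = enc.batch_graphs([enc.build_graph(rec)])
        p = enc.init_encoder_params(7, 3, 0.0, rng=np.random.default_rng(3))
        F, _ = enc.encode_sites(batch, p, training=False)
        atom_rows = F[:6]
        np.testing.assert_allclose(
            atom_rows, np.broadcast_to(atom_rows[0], atom_rows.shape), atol=1e-10
        )

    def test_atom_and_bond_embeddings_share_width(self):
        rec = record_from_smiles("CCS", "m")
        batch = enc.batch_graphs([enc.build_graph(rec)])
        p = enc.init_encoder_params(11, 2, 0.0, rng=np.random.default_rng(4))
        F, _ = enc.encode_sites(batch, p, training=False)
        assert F.shape == (batch.n_sites, 11)


class TestPermutationEquivariance:
    def test_renumbering_permutes_site_embeddings(self):
        smiles = "CSc1ccc(O)cc1"
        rec = record_from_smiles(smiles, "m")
        perm = [
            int(i)
            for i in np.random.default_rng(11).permutation(rec.mol.GetNumAtoms())
        ]
        mol2 = Chem.RenumberAtoms(rec.mol, perm)
        rec2 = record_from_smiles(Chem.MolToSmiles(mol2), "m2")
        rec2.mol = mol2
        p = enc.init_encoder_params(10, 3, 0.0, rng=np.random.default_rng(8))
        b1 = enc.batch_graphs([enc.build_graph(rec)])
        b2 = enc.batch_graphs([enc.build_graph(rec2)])
        F1, _ = enc.encode_sites(b1, p, training=False)
        F2, _ = enc.encode_sites(b2, p, training=False)
        inv = {old: new for new, old in enumerate(perm)}
        map2 = {}
        for row, site in enumerate(b2.sites):
            map2[site] = row
        from cypsom.chem import SiteKey

        for row, site in enumerate(b1.sites):
            if site.kind == "bond":
                mapped = SiteKey.bond(inv[site.a], inv[site.b])
            elif site.kind == "atom":
                mapped = SiteKey.atom(inv[site.a])
            else:
                mapped = SiteKey.hbond(inv[site.a])
            np.testing.assert_allclose(F1[row], F2[map2[mapped]], atol=1e-9)


class TestMoleculeEmbedding:
    def test_single_heavy_atom_pooling_is_identity(self):
        rec = record_from_smiles("C", "methane")
        batch = enc.batch_graphs([enc.build_graph(rec)])
        rng = np.random.default_rng(0)
        mp = enc.init_molecule_encoder_params(5, 1, 5, rng=rng)
        mp.W_pool = np.eye(5)
        mv, _ = enc.molecule_embedding(batch, mp)
        atom_all, _ = enc.readout_atom(
            _final_states(batch, mp.core), batch, mp.core
        )
        np.testing.assert_allclose(mv[0], atom_all[batch.heavy_index][0])

    def test_embedding_is_permutation_invariant(self):
        rec = record_from_smiles("CC(O)CSC", "m")
        perm = [3, 1, 4, 0, 2, 5][: rec.mol.GetNumAtoms()]
        mol2 = Chem.RenumberAtoms(rec.mol, perm)
        rec2 = record_from_smiles(Chem.MolToSmiles(mol2), "m2")
        rec2.mol = mol2
        mp = enc.init_molecule_encoder_params(6, 2, 4, rng=np.random.default_rng(1))
        mv1, _ = enc.molecule_embedding(enc.batch_graphs([enc.build_graph(rec)]), mp)
        mv2, _ = enc.molecule_embedding(enc.batch_graphs([enc.build_graph(rec2)]), mp)
        np.testing.assert_allclose(mv1, mv2, atol=1e-9)


def _final_states(batch, params):
    h0, _ = enc.init_messages(batch, params)
    h = h0
    for _ in range(params.depth):
        h, _ = enc.message_pass(h, h0, batch, params)
    return h


class TestHeadAndLoss:
    def test_zero_weights_give_half_half(self):
        head = enc.HeadParams(W=np.zeros((2, 4)), b=np.zeros(2))
        probs = enc.probability_head(np.random.default_rng(0).random((5, 4)), head)
        np.testing.assert_allclose(probs, 0.5)

    def test_probabilities_sum_to_one_and_are_monotone(self):
        rng = np.random.default_rng(1)
        head = enc.HeadParams(W=rng.standard_normal((2, 3)), b=rng.standard_normal(2))
        F = rng.standard_normal((20, 3))
        probs = enc.probability_head(F, head)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)
        assert np.all((probs >= 0) & (probs <= 1))
        # raising the positive logit raises p_positive
        head2 = enc.HeadParams(W=head.W.copy(), b=head.b + np.array([1.0, 0.0]))
        probs2 = enc.probability_head(F, head2)
        assert np.all(probs2[:, 0] > probs[:, 0])

    def test_equal_weights_reduce_to_plain_cross_entropy(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet([1, 1], size=30)
        y = rng.integers(0, 2, 30)
        expected = -np.sum(np.log(np.where(y == 1, probs[:, 0], probs[:, 1])))
        got = enc.weighted_loss(probs, y, enc.LossWeights(1, 1))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_perfect_predictions_give_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert enc.weighted_loss(probs, [1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_weighted_example(self):
        """One positive and one negative both at p=0.5 with a=2, b=1 give
        3*ln(2)."""
        probs = np.array([[0.5, 0.5], [0.5, 0.5]])
        got = enc.weighted_loss(probs, [1, 0], enc.LossWeights(2, 1))
        assert got == pytest.approx(3 * np.log(2), rel=1e-12)

    def test_empty_batch_is_an_error(self):
        with pytest.raises(ValueError):
            enc.weighted_loss(np.zeros((0, 2)), [])

    def test_invalid_loss_weights_rejected(self):
        from cypsom.errors import ConfigError

        with pytest.raises(ConfigError):
            enc.LossWeights(0, 0)


class TestReproducibility:
    def test_eval_forward_is_bitwise_reproducible(self, planted_dataset):
        batch = enc.batch_graphs(
            [enc.build_graph(r) for r in planted_dataset[:5]]
        )
        p = enc.init_encoder_params(8, 2, 0.05, rng=np.random.default_rng(6))
        F1, _ = enc.encode_sites(batch, p, training=False)
        F2, _ = enc.encode_sites(batch, p, training=False)
        assert np.array_equal(F1, F2)
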