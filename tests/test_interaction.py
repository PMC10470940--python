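import numpy as np
import pytest

from subcdr.interaction import (GCNParams, InteractionMap, build_graph,
                                gcn_forward, graph_matrices,
                                normalized_propagation_matrix, pool,
                                score_interactions)


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


class TestScoreInteractions:
    def test_zero_bilinear_gives_half_everywhere(self):
        imap = score_interactions(np.ones((3, 2)), np.ones((4, 2)),
                                  np.zeros((2, 2)))
        assert np.allclose(imap.scores, 0.5)

    def test_ln3_logit_gives_three_quarters(self):
        d = np.array([[1.0]])
        c = np.array([[1.0]])
        omega = np.array([[np.log(3.0)]])
        imap = score_interactions(d, c, omega)
        assert np.isclose(imap.scores[0, 0], 0.75)

    def test_matches_elementwise_hand_computation(self):
        rng = np.random.default_rng(0)
        d, c, omega = rng.normal(size=(3, 4)), rng.normal(size=(2, 4)), \
            rng.normal(size=(4, 4))
        imap = score_interactions(d, c, omega)
        for i in range(3):
            for j in range(2):
                logit = sum(d[i, a] * omega[a, b] * c[j, b]
                            for a in range(4) for b in range(4))
                assert np.isclose(imap.scores[i, j], _sigmoid(logit),
                                  atol=1e-8)

    def test_pad_mask_removes_rows(self):
        rng = np.random.default_rng(1)
        imap = score_interactions(rng.normal(size=(4, 3)),
                                  rng.normal(size=(2, 3)),
                                  rng.normal(size=(3, 3)),
                                  pad_mask=[1, 1, 0, 0])
        assert imap.shape == (2, 2)

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError, match="width"):
            score_interactions(np.ones((3, 4)), np.ones((2, 5)),
                               np.eye(4))

    def test_scores_bounded_in_open_interval(self):
        rng = np.random.default_rng(2)
        imap = score_interactions(rng.normal(size=(5, 3)) * 100,
                                  rng.normal(size=(4, 3)) * 100,
                                  rng.normal(size=(3, 3)) * 100)
        assert np.all(imap.scores > 0) and np.all(imap.scores < 1)

    def test_scaling_omega_moves_scores_from_half_monotonically(self):
        rng = np.random.default_rng(3)
        d, c, om = rng.normal(size=(3, 4)), rng.normal(size=(2, 4)), \
            rng.normal(size=(4, 4))
        s1 = score_interactions(d, c, om).scores
        s2 = score_interactions(d, c, 2.0 * om).scores
        assert np.all(np.abs(s2 - 0.5) >= np.abs(s1 - 0.5) - 1e-12)
        assert np.all(np.sign(s2 - 0.5) == np.sign(s1 - 0.5))


class TestGraph:
    def test_2x3_map_counts(self):
        imap = InteractionMap(np.full((2, 3), 0.4))
        g = build_graph(imap)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 6
        _, _, x = graph_matrices(g)
        assert np.array_equal(x, np.eye(5))

    def test_1x1_map(self):
        imap = InteractionMap(np.array([[0.7]]))
        g = build_graph(imap)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.edges[("d", 0), ("c", 0)]["weight"] == pytest.approx(0.7)

    def test_invalid_map_rejected(self):
        with pytest.raises(ValueError):
            InteractionMap(np.array([[1.2]]))
        with pytest.raises(ValueError):
            InteractionMap(np.empty((0, 2)))


def _brute_force_gcn(g, params):
    """Independent per-node implementation of the propagation rule."""
    nodes = sorted(g.nodes, key=lambda v: g.nodes[v]["onehot"])
    nv = len(nodes)
    z = np.eye(nv)
    k_last = len(params.thetas) - 1
    for k, theta in enumerate(params.thetas):
        new = np.zeros((nv, np.asarray(theta).shape[0]))
        for vi, v in enumerate(nodes):
            qv = 1 + g.degree(v)
            acc = np.zeros(np.asarray(theta).shape[0])
            for u in list(g.neighbors(v)) + [v]:
                ui = g.nodes[u]["onehot"]
                a = 1.0 if u == v else g.edges[v, u]["weight"]
                qu = 1 + g.degree(u)
                denom = qv * qu
                if params.norm == "sym_sqrt":
                    denom = np.sqrt(denom)
                acc += (a / denom) * (np.asarray(theta) @ z[ui])
            new[vi] = acc
        if not params.simplified or k == k_last:
            new = np.where(new > 0, new, params.leaky_slope * new)
        z = new
    return z


class TestGCN:
    def test_two_node_graph_hand_evaluation(self):
        imap = InteractionMap(np.array([[0.999999999]]))
        g = build_graph(imap)
        theta = np.eye(2)
        params = GCNParams([theta], activation="linear")
        z = gcn_forward(g, params)
        # both nodes: q = 2; self (a=1) plus neighbour (a~1):
        # z_d = (1/4)*e_d + (1/4)*e_c
        assert np.allclose(z, [[0.25, 0.25], [0.25, 0.25]], atol=1e-6)

    def test_zero_theta_zero_embeddings(self):
        imap = InteractionMap(np.full((2, 3), 0.3))
        params = GCNParams([np.zeros((4, 5)), np.zeros((4, 4))])
        z = gcn_forward(build_graph(imap), params)
        assert np.allclose(z, 0.0)

    @pytest.mark.parametrize("norm", ["product", "sym_sqrt"])
    @pytest.mark.parametrize("simplified", [False, True])
    def test_matches_brute_force_oracle(self, norm, simplified):
        rng = np.random.default_rng(4)
        imap = InteractionMap(rng.uniform(0.05, 0.95, size=(3, 3)))
        g = build_graph(imap)
        thetas = [rng.normal(size=(4, 6)), rng.normal(size=(2, 4))]
        params = GCNParams(thetas, norm=norm, simplified=simplified)
        assert np.allclose(gcn_forward(g, params),
                           _brute_force_gcn(g, params), atol=1e-8)

    def test_permutation_equivariance_of_fragment_rows(self):
        # permuting the drug fragments permutes map rows; running the
        # GCN with the attribute basis permuted the same way leaves the
        # node embeddings (up to row order) and the pooled summary
        # unchanged
        rng = np.random.default_rng(5)
        scores = rng.uniform(0.1, 0.9, size=(3, 2))
        thetas = [rng.normal(size=(3, 5))]
        perm = [2, 0, 1]
        z1 = gcn_forward(build_graph(InteractionMap(scores)),
                         GCNParams(thetas))
        thetas_p = [thetas[0][:, perm + [3, 4]]]
        z2 = gcn_forward(build_graph(InteractionMap(scores[perm])),
                         GCNParams(thetas_p))
        assert np.allclose(z1[perm], z2[:3], atol=1e-10)
        assert np.allclose(z1[3:], z2[3:], atol=1e-10)
        assert np.allclose(pool(z1), pool(z2), atol=1e-10)

    def test_empty_layer_list_rejected(self):
        with pytest.raises(ValueError):
            GCNParams([])


class TestPool:
    def test_single_row(self):
        z = np.array([[1.0, -2.0]])
        assert np.allclose(pool(z), [1.0, -2.0, 1.0, -2.0])

    def test_max_and_mean_example(self):
        z = np.array([[0.0, 2.0], [4.0, 0.0]])
        assert np.allclose(pool(z), [4.0, 2.0, 2.0, 1.0])

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(5, 3))
        assert np.allclose(pool(z), pool(z[::-1]))


def test_propagation_matrix_norms():
    adj = np.array([[1.0, 0.5], [0.5, 1.0]])
    n_prod = normalized_propagation_matrix(adj, "product")
    n_sqrt = normalized_propagation_matrix(adj, "sym_sqrt")
    assert np.allclose(n_prod, adj / 4.0)
    assert np.allclose(n_sqrt, adj / 2.0)
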