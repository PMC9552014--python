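"""Network building blocks against straight-line oracles and analytic values."""

import math

import numpy as np
import pytest

from mvifmda.autodiff import Tensor
from mvifmda.model import (
    MVIFMDA,
    ModelConfig,
    attention_fuse,
    bce_loss,
    bilinear_decode,
    cnn_encode,
    concat_embeddings,
    gcn_forward,
    normalize_adjacency,
)
from mvifmda.netbuild import assemble_hetero_networks


class TestNormalizeAdjacency:
    def test_identity_is_fixed_point(self):
        np.testing.assert_allclose(normalize_adjacency(np.eye(4)), np.eye(4))

    def test_all_ones_two_by_two(self):
        np.testing.assert_allclose(
            normalize_adjacency(np.ones((2, 2))), 0.5 * np.ones((2, 2)))

    def test_symmetric_input_gives_symmetric_output(self):
        rng = np.random.default_rng(3)
        M = np.abs(rng.normal(size=(6, 6)))
        M = M + M.T
        out = normalize_adjacency(M)
        np.testing.assert_allclose(out, out.T)

    def test_isolated_node_stays_finite(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 1.0
        assert np.isfinite(normalize_adjacency(M)).all()

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            normalize_adjacency(-np.eye(2))


def straight_line_gcn(M, weights, n_layers):
    """Independent dense re-implementation with explicit loops, no classes."""
    n = M.shape[0]
    d = M.sum(axis=1)
    G = np.zeros_like(M, dtype=float)
    for i in range(n):
        for j in range(n):
            G[i, j] = M[i, j] / math.sqrt(max(d[i], 1e-12)) / math.sqrt(
                max(d[j], 1e-12))
    X = M.astype(float)
    outs = []
    for l in range(n_layers):
        X = G @ X @ weights[l]
        X = np.where(X > 0, X, 0.0)  # ReLU
        outs.append(X.copy())
    return outs


class TestGCNForward:
    def test_zero_weights_give_zero_outputs(self):
        M = np.ones((3, 3))
        weights = [Tensor(np.zeros((3, 2))), Tensor(np.zeros((2, 2)))]
        outs = gcn_forward(normalize_adjacency(M), M, weights)
        for o in outs:
            np.testing.assert_array_equal(o.data, 0.0)

    def test_single_node_scalar_case(self):
        m, w = 2.0, 0.7
        # degree-normalized 1x1 adjacency is m / m = 1
        out = gcn_forward(np.array([[1.0]]), np.array([[m]]),
                          [Tensor(np.array([[w]]))])
        assert out[0].data[0, 0] == pytest.approx(max(m / m * m * w, 0.0))

    @pytest.mark.parametrize("n_layers", [1, 2, 3])
    def test_matches_straight_line_oracle_on_random_graphs(self, n_layers):
        rng = np.random.default_rng(17 + n_layers)
        for _ in range(5):
            M = np.abs(rng.normal(size=(5, 5)))
            M = M + M.T
            widths = [5, 4, 3, 2][: n_layers + 1]
            weights = [
                Tensor(rng.normal(size=(widths[i], widths[i + 1])))
                for i in range(n_layers)
            ]
            outs = gcn_forward(normalize_adjacency(M), M, weights)
            expected = straight_line_gcn(M, [w.data for w in weights], n_layers)
            for got, want in zip(outs, expected):
                np.testing.assert_allclose(got.data, want, atol=1e-6)

    def test_width_mismatch_raises(self):
        M = np.ones((3, 3))
        with pytest.raises(ValueError):
            gcn_forward(normalize_adjacency(M), M, [Tensor(np.zeros((4, 2)))])


class TestAttentionFuse:
    def _params(self, f, seed=0):
        rng = np.random.default_rng(seed)
        return (Tensor(rng.normal(size=(f, f))), Tensor(rng.normal(size=f)),
                Tensor(rng.normal(size=(f, 1))))

    def test_single_representation_passes_through(self):
        Wa, ba, qa = self._params(3)
        x = Tensor(np.arange(12.0).reshape(4, 3))
        fused, beta = attention_fuse([x], Wa, ba, qa)
        np.testing.assert_allclose(beta, [1.0])
        np.testing.assert_allclose(fused.data, x.data)

    def test_identical_representations_share_weight_equally(self):
        Wa, ba, qa = self._params(2, seed=4)
        x = np.array([[1.0, -2.0], [0.5, 3.0]])
        fused, beta = attention_fuse([Tensor(x), Tensor(x.copy())], Wa, ba, qa)
        np.testing.assert_allclose(beta, [0.5, 0.5])
        np.testing.assert_allclose(fused.data, x, rtol=1e-12)

    def test_weights_form_probability_vector(self):
        Wa, ba, qa = self._params(4, seed=9)
        rng = np.random.default_rng(10)
        reps = [Tensor(rng.normal(size=(6, 4))) for _ in range(7)]
        _, beta = attention_fuse(reps, Wa, ba, qa)
        assert beta.sum() == pytest.approx(1.0)
        assert (beta > 0).all()

    def test_fusion_stays_in_entrywise_convex_hull(self):
        Wa, ba, qa = self._params(3, seed=2)
        rng = np.random.default_rng(11)
        reps = [Tensor(rng.uniform(-1, 1, size=(5, 3))) for _ in range(4)]
        fused, _ = attention_fuse(reps, Wa, ba, qa)
        stack = np.stack([r.data for r in reps])
        assert (fused.data >= stack.min(axis=0) - 1e-12).all()
        assert (fused.data <= stack.max(axis=0) + 1e-12).all()

    def test_empty_stack_rejected(self):
        Wa, ba, qa = self._params(2)
        with pytest.raises(ValueError, match="empty"):
            attention_fuse([], Wa, ba, qa)


class TestCNNEncode:
    def test_zero_filters_and_bias_give_zeros(self):
        views = [np.ones((4, 4)), np.eye(4)]
        out = cnn_encode(views, Tensor(np.zeros((4, 3))),
                         Tensor(np.zeros((4, 3))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_one_hot_filter_selects_a_row(self):
        rng = np.random.default_rng(6)
        S = rng.uniform(size=(5, 5))
        r = 2
        w = np.zeros((5, 1))
        w[r, 0] = 1.0
        out = cnn_encode([S], Tensor(w), Tensor(np.zeros((5, 1))))
        np.testing.assert_allclose(out.data[:, 0], S[r, :])

    def test_output_shape_is_entities_by_channels(self):
        views = [np.eye(6), np.ones((6, 6))]
        out = cnn_encode(views, Tensor(np.zeros((6, 8))),
                         Tensor(np.zeros((6, 8))))
        assert out.data.shape == (6, 8)

    def test_non_square_view_rejected(self):
        with pytest.raises(ValueError, match="square"):
            cnn_encode([np.ones((3, 4))], Tensor(np.zeros((3, 2))),
                       Tensor(np.zeros((3, 2))))


class TestConcatAndDecode:
    def test_concat_width_adds_up_and_preserves_columns(self):
        a = Tensor(np.arange(6.0).reshape(3, 2))
        b = Tensor(np.arange(9.0).reshape(3, 3))
        out = concat_embeddings(a, b)
        assert out.data.shape == (3, 5)
        np.testing.assert_array_equal(out.data[:, :2], a.data)
        np.testing.assert_array_equal(out.data[:, 2:], b.data)

    def test_missing_branch_passes_the_other_through(self):
        a = Tensor(np.ones((2, 4)))
        assert concat_embeddings(a, None) is a
        assert concat_embeddings(None, a) is a
        with pytest.raises(ValueError):
            concat_embeddings(None, None)

    def test_zero_interaction_matrix_scores_half_everywhere(self):
        Zm = Tensor(np.random.default_rng(0).normal(size=(4, 3)))
        Zd = Tensor(np.random.default_rng(1).normal(size=(2, 3)))
        scores = bilinear_decode(Zm, Zd, Tensor(np.zeros((3, 3))))
        np.testing.assert_array_equal(scores.data, 0.5 * np.ones((4, 2)))

    def test_scalar_case(self):
        scores = bilinear_decode(Tensor(np.array([[2.0]])),
                                 Tensor(np.array([[3.0]])),
                                 Tensor(np.array([[1.0]])))
        assert scores.data[0, 0] == pytest.approx(1 / (1 + math.exp(-6.0)))

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        Zm, Zd = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        Wb = rng.normal(size=(3, 3))
        base = bilinear_decode(Tensor(Zm), Tensor(Zd), Tensor(Wb)).data
        perm = rng.permutation(5)
        shuffled = bilinear_decode(Tensor(Zm[perm]), Tensor(Zd),
                                   Tensor(Wb)).data
        np.testing.assert_allclose(shuffled, base[perm])


class TestLoss:
    def test_uniform_half_scores_give_analytic_value(self):
        nm, nd = 7, 5
        scores = Tensor(0.5 * np.ones((nm, nd)))
        A = np.zeros((nm, nd))
        A[0, 0] = A[3, 2] = 1
        assert float(bce_loss(scores, A).data) == pytest.approx(
            nm * nd * math.log(2.0))

    def test_perfect_scores_drive_loss_to_zero(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        eps = 1e-9
        scores = Tensor(np.where(A == 1, 1 - eps, eps))
        assert float(bce_loss(scores, A).data) < 1e-7

    def test_two_by_two_term_by_term_oracle(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        P = np.array([[0.8, 0.3], [0.25, 0.6]])
        expected = -(math.log(0.8) + math.log(0.7) + math.log(0.75)
                     + math.log(0.4))
        assert float(bce_loss(Tensor(P), A).data) == pytest.approx(expected)

    def test_boundary_scores_clamped_with_warning(self):
        A = np.zeros((1, 2))
        with pytest.warns(UserWarning, match="clamped"):
            val = float(bce_loss(Tensor(np.array([[0.0, 1.0]])), A).data)
        assert np.isfinite(val) and val >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            bce_loss(Tensor(np.full((2, 2), 0.5)), np.zeros((3, 2)))


class TestFullModel:
    def _build(self, small_views, **kw):
        assoc, sms, sds = small_views
        cfg = ModelConfig(f_topology=8, f_channel=6, seed=5, **kw)
        model = MVIFMDA(cfg, assoc.n_mirna, assoc.n_disease)
        nets = assemble_hetero_networks(assoc, sms, sds)
        return model, model.prepare_inputs(nets, sms, sds), assoc

    def test_forward_shape_and_open_interval(self, small_views):
        model, inputs, assoc = self._build(small_views)
        scores = model.predict(inputs)
        assert scores.shape == (assoc.n_mirna, assoc.n_disease)
        assert (scores > 0).all() and (scores < 1).all()

    def test_same_seed_reproduces_scores(self, small_views):
        m1, i1, _ = self._build(small_views)
        m2, i2, _ = self._build(small_views)
        np.testing.assert_allclose(m1.predict(i1), m2.predict(i2), atol=1e-7)

    def test_ablation_embedding_widths(self):
        full = ModelConfig(f_topology=8, f_channel=6)
        no_topology = ModelConfig(f_topology=8, f_channel=6,
                                  use_topology=False)
        no_attribute = ModelConfig(f_topology=8, f_channel=6,
                                   use_attribute=False)
        assert full.embedding_width == 14
        assert no_topology.embedding_width == 6     # attribute-only variant
        assert no_attribute.embedding_width == 8    # topology-only variant
        with pytest.raises(ValueError):
            ModelConfig(use_topology=False, use_attribute=False)

    @pytest.mark.parametrize("kw", [
        {}, {"use_topology": False}, {"use_attribute": False}])
    def test_ablation_variants_run_and_checkpoint(self, small_views, kw):
        model, inputs, assoc = self._build(small_views, **kw)
        scores = model.predict(inputs)
        clone = MVIFMDA(ModelConfig(f_topology=8, f_channel=6, seed=99, **kw),
                        assoc.n_mirna, assoc.n_disease)
        clone.load_state_dict(model.state_dict())
        np.testing.assert_array_equal(clone.predict(inputs), scores)

    def test_attention_weights_recorded(self, small_views):
        model, inputs, _ = self._build(small_views)
        model.predict(inputs)
        beta = model.attention_weights_
        assert beta.shape == (4 * model.config.n_layers,)
        assert beta.sum() == pytest.approx(1.0)
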