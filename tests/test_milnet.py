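"""Model mathematics: closed-form oracles for each operation, architecture
identities (SA-eval = SAB, DIP with K >= N = SAB, tied-branch MAB = uniform),
permutation invariance, sampling statistics, and finite-difference checks of
every analytic gradient."""

import numpy as np
import pytest

from attnmil import milnet
from attnmil.milnet import (
    MILModel,
    ModelConfig,
    aggregate,
    attention_weights,
    dip_select,
    gated_attention_scores,
    init_params,
    sab_forward,
    sa_forward,
    stochastic_sample,
    transform_features,
)


def _model(arch="sab", seed=0, **kw):
    defaults = dict(arch=arch, in_dim=12, n_classes=3, hidden_dim=8, attn_dim=5,
                    dropout=0.0)
    defaults.update(kw)
    return MILModel(ModelConfig(**defaults), seed=seed)


@pytest.fixture
def X(rng):
    return rng.standard_normal((20, 12))


class TestTransform:
    def test_relu_and_matvec_oracle(self, rng):
        X = rng.standard_normal((2, 3))
        W = rng.standard_normal((3, 4))
        b = rng.standard_normal(4)
        H, _ = transform_features(X, W, b)
        np.testing.assert_allclose(H, np.maximum(X @ W + b, 0.0), rtol=1e-12)

    def test_all_negative_preactivations_zero(self):
        H, _ = transform_features(np.ones((3, 2)), -np.eye(2), np.zeros(2))
        assert (H == 0).all()

    def test_identity_passthrough_for_nonnegative(self):
        X = np.abs(np.random.default_rng(1).standard_normal((4, 3)))
        H, _ = transform_features(X, np.eye(3), np.zeros(3))
        np.testing.assert_array_equal(H, X)


class TestGatedAttention:
    def test_zero_features_zero_scores(self, rng):
        # tanh(0) = 0 annihilates the gated product regardless of w, U
        p = init_params(ModelConfig(arch="sab", in_dim=4, n_classes=2,
                                    hidden_dim=4, attn_dim=3), seed=1)
        p["bv"][:] = 0
        a, _ = gated_attention_scores(np.zeros((5, 4)), p["V"], p["bv"],
                                      p["U"], p["bu"], p["w"], np.zeros(()))
        np.testing.assert_allclose(a, 0.0, atol=1e-15)

    def test_scalar_closed_form(self):
        # attn_dim=1: a = w * tanh(V h) * sigmoid(U h) with U = 0 -> gate 0.5
        V = np.array([[1.0]])
        U = np.array([[0.0]])
        w = np.array([2.0])
        a, _ = gated_attention_scores(np.array([[0.5]]), V, np.zeros(1),
                                      U, np.zeros(1), w, np.zeros(()))
        assert a[0] == pytest.approx(2 * np.tanh(0.5) * 0.5, abs=1e-12)
        assert a[0] == pytest.approx(0.4621, abs=1e-4)

    def test_tied_mab_branches_identical_columns(self, rng):
        c, a_dim, l = 4, 3, 6
        V = np.broadcast_to(rng.standard_normal((a_dim, l)), (c, a_dim, l)).copy()
        U = np.broadcast_to(rng.standard_normal((a_dim, l)), (c, a_dim, l)).copy()
        w = np.broadcast_to(rng.standard_normal(a_dim), (c, a_dim)).copy()
        H = rng.standard_normal((7, l))
        scores, _ = gated_attention_scores(H, V, np.zeros((c, a_dim)),
                                           U, np.zeros((c, a_dim)), w, np.zeros(c))
        for j in range(1, c):
            np.testing.assert_array_equal(scores[:, 0], scores[:, j])


class TestWeightsAndAggregate:
    def test_uniform_for_equal_scores(self):
        np.testing.assert_allclose(attention_weights(np.full(7, 3.2)), np.full(7, 1 / 7))

    def test_analytic_two_point(self):
        np.testing.assert_allclose(attention_weights(np.array([0.0, np.log(3)])),
                                   [0.25, 0.75], rtol=1e-12)

    def test_shift_invariance(self, rng):
        a = rng.standard_normal(10)
        np.testing.assert_allclose(attention_weights(a), attention_weights(a + 1000.0),
                                   rtol=1e-12)

    def test_aggregate_oracles(self, rng):
        H = rng.standard_normal((3, 5))
        np.testing.assert_allclose(aggregate(H[:1], np.ones(1)), H[0], rtol=1e-12)
        np.testing.assert_allclose(aggregate(H, np.full(3, 1 / 3)), H.mean(0), rtol=1e-12)
        w = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(aggregate(H, w),
                                   0.2 * H[0] + 0.3 * H[1] + 0.5 * H[2], rtol=1e-12)


class TestArchitectureIdentities:
    def test_sa_eval_equals_sab_bitwise(self, rng):
        m = _model("sa", k=4)
        for _ in range(50):
            X = rng.standard_normal((rng.integers(5, 40), 12))
            p1 = sa_forward(X, m.params, m.config, mode="eval",
                            rng=np.random.default_rng(123))
            p2 = sab_forward(X, m.params, m.config, mode="eval")
            assert (p1.probs == p2.probs).all()  # bit-for-bit

    def test_sa_train_k_equals_n_matches_sab_train(self, X):
        m = _model("sa", k=20, dropout=0.25)
        p1 = sa_forward(X, m.params, m.config, mode="train", rng=np.random.default_rng(9))
        p2 = sab_forward(X, m.params, m.config, mode="train", rng=np.random.default_rng(9))
        np.testing.assert_array_equal(p1.probs, p2.probs)

    def test_dip_with_large_k_equals_sab(self, X):
        m = _model("dip", top_k=1000)
        p1 = m.forward(X)
        p2 = sab_forward(X, m.params, m.config)
        np.testing.assert_array_equal(p1.probs, p2.probs)
        np.testing.assert_array_equal(p1.attention.kept_indices, np.arange(len(X)))

    def test_tied_mab_gives_uniform_probs(self, rng):
        m = _model("mab")
        for key in ("V", "U", "bv", "bu", "w"):
            m.params[key][:] = m.params[key][0]
        m.params["Wc"][:] = m.params["Wc"][0]
        m.params["bc"][:] = 0.0
        pred = m.forward(rng.standard_normal((15, 12)))
        np.testing.assert_allclose(pred.probs, 1 / 3, atol=1e-12)

    def test_zero_classifier_uniform_probs(self, X):
        m = _model("sab")
        m.params["Wc"][:] = 0.0
        m.params["bc"][:] = 0.0
        np.testing.assert_allclose(m.forward(X).probs, 1 / 3, atol=1e-15)

    def test_duplicated_instances_same_prediction(self, X):
        m = _model("sab")
        p1 = m.forward(X)
        p2 = m.forward(np.vstack([X, X]))
        np.testing.assert_allclose(p1.probs, p2.probs, atol=1e-12)
        np.testing.assert_allclose(p2.attention.weights.sum(), 1.0, atol=1e-9)

    @pytest.mark.parametrize("arch,kw", [("sab", {}), ("mab", {}),
                                         ("dip", {"top_k": 8}), ("sa", {"k": 4})])
    def test_eval_permutation_invariance(self, arch, kw, X, rng):
        m = _model(arch, **kw)
        perm = rng.permutation(len(X))
        p1 = m.forward(X)
        p2 = m.forward(X[perm])
        np.testing.assert_allclose(p1.probs, p2.probs, atol=1e-6)

    @pytest.mark.parametrize("arch,kw", [("sab", {}), ("mab", {}),
                                         ("dip", {"top_k": 8}), ("sa", {"k": 4})])
    def test_weight_columns_sum_to_one(self, arch, kw, X):
        pred = _model(arch, **kw).forward(X)
        np.testing.assert_allclose(pred.attention.weights.sum(axis=0), 1.0, atol=1e-6)
        assert (pred.attention.weights >= 0).all()
        assert pred.probs.sum() == pytest.approx(1.0, abs=1e-6)


class TestDipSelect:
    def _scorer(self, scores):
        # rig a scorer that reproduces the given per-instance scores from
        # one-hot features: Ws1 = I, Ws2 = scores work when scores >= 0
        n = len(scores)
        return dict(Ws1=np.eye(n), bs1=np.zeros(n), Ws2=np.asarray(scores, float),
                    bs2=np.zeros(()))

    def test_topk_sort_oracle(self):
        p = self._scorer([3.0, 1.0, 2.0])
        idx, _ = dip_select(np.eye(3), p["Ws1"], p["bs1"], p["Ws2"], p["bs2"], top_k=2)
        assert idx.tolist() == [0, 2]

    def test_tie_break_lowest_index(self):
        p = self._scorer([1.0, 1.0, 1.0])
        idx, _ = dip_select(np.eye(3), p["Ws1"], p["bs1"], p["Ws2"], p["bs2"], top_k=2)
        assert idx.tolist() == [0, 1]

    def test_empty_bag_rejected(self):
        p = self._scorer([1.0])
        with pytest.raises(ValueError):
            dip_select(np.zeros((0, 1)), p["Ws1"], p["bs1"], p["Ws2"], p["bs2"], 1)


class TestStochasticSample:
    def test_dominant_weight_always_selected(self):
        alpha = attention_weights(np.array([30.0] + [0.0] * 9))
        rng = np.random.default_rng(0)
        hits = sum(stochastic_sample(alpha, 1, rng)[0][0] == 0 for _ in range(10_000))
        assert hits / 10_000 >= 0.999

    def test_k_equals_n_returns_original_weights(self, rng):
        alpha = attention_weights(rng.standard_normal(8))
        idx, w = stochastic_sample(alpha, 8, rng)
        np.testing.assert_array_equal(idx, np.arange(8))
        np.testing.assert_allclose(w, alpha, rtol=1e-12)

    def test_uniform_frequencies_binomial_ci(self):
        alpha = np.full(4, 0.25)
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        for _ in range(100_000):
            counts[stochastic_sample(alpha, 1, rng)[0][0]] += 1
        np.testing.assert_allclose(counts / 100_000, 0.25, atol=0.01)

    def test_sampled_aggregate_tracks_deterministic_mean(self, rng):
        # the renormalized subset average is exactly unbiased for k=1
        # (selection probability alpha_i, weight 1), exact at k=N, and stays
        # within a bounded band of the deterministic aggregate in between
        # (the without-replacement renormalization is biased for 1 < k < N)
        H = rng.standard_normal((50, 6))
        alpha = attention_weights(rng.standard_normal(50) * 0.3)
        M_det = alpha @ H
        scale = np.abs(M_det).max()

        def mc_mean(k, reps=10_000):
            draws = np.empty((reps, 6))
            for r in range(reps):
                idx, beta = stochastic_sample(alpha, k, rng)
                draws[r] = beta @ H[idx]
            return draws.mean(0), draws.std(0) / np.sqrt(reps)

        mean1, se1 = mc_mean(1)
        assert (np.abs(mean1 - M_det) < 4 * se1 + 1e-12).all()   # unbiased case
        assert np.abs(mc_mean(4)[0] - M_det).max() / scale < 0.25  # bounded bias
        idx, beta = stochastic_sample(alpha, 50, rng)
        np.testing.assert_allclose(beta @ H[idx], M_det, rtol=1e-12)  # k = N exact


class TestGradients:
    @pytest.mark.parametrize("arch,kw", [("sab", {}), ("mab", {}),
                                         ("dip", {"top_k": 8}), ("sa", {"k": 5})])
    def test_analytic_matches_finite_difference(self, arch, kw, rng):
        X = rng.standard_normal((15, 12))
        m = _model(arch, seed=3, dropout=0.25, **kw)
        fixed = lambda: np.random.default_rng(42)
        _, grads, _ = m.loss_and_gradients(X, 1, mode="train", rng=fixed())
        eps = 1e-6
        for key, v in m.params.items():
            flat = v.ravel()
            pick = np.random.default_rng(1).choice(flat.size,
                                                   size=min(6, flat.size), replace=False)
            for j in pick:
                orig = flat[j]
                flat[j] = orig + eps
                lp = m.loss_and_gradients(X, 1, mode="train", rng=fixed())[0]
                flat[j] = orig - eps
                lm = m.loss_and_gradients(X, 1, mode="train", rng=fixed())[0]
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[key].ravel()[j]) < 1e-6, (arch, key)

    def test_gradient_flow_through_attention(self, X):
        m = _model("sab")
        _, grads, _ = m.loss_and_gradients(X, 0, mode="train",
                                           rng=np.random.default_rng(0))
        for key in ("V", "U", "w", "W1", "Wc"):
            assert np.abs(grads[key]).max() > 0


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, X):
        m = _model("sa", k=7)
        p1 = m.forward(X)
        milnet.save_checkpoint(m, tmp_path / "ckpt")
        m2 = milnet.load_checkpoint(tmp_path / "ckpt")
        assert m2.config == m.config
        np.testing.assert_array_equal(m2.forward(X).probs, p1.probs)
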