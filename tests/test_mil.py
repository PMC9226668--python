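"""Unit tests for the gated-attention MIL model against loop oracles and
closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemamil.mil import (
    GatedAttentionMIL,
    MilConfig,
    MilParams,
    _forward_backward,
    attention_scores,
    embed,
    forward,
    init_params,
    instance_cluster_loss,
    load_checkpoint,
    save_checkpoint,
    select_instances,
    slide_score,
    smooth_top1_svm_loss,
    total_loss,
)


def loop_forward(x, params):
    """Scalar-loop re-implementation of the full forward pass: gated
    attention scores, patch softmax, weighted slide representation and
    class logits.  No matrix library calls on purpose."""
    K, D = x.shape
    E = params.fc1_w.shape[0]
    A_dim = params.attn1_w.shape[0]
    N = params.heads_w.shape[0]
    H = [[0.0] * E for _ in range(K)]
    for k in range(K):
        a1 = [max(0.0, sum(params.fc1_w[e][d] * x[k][d] for d in range(D))
                  + params.fc1_b[e]) for e in range(E)]
        for e in range(E):
            H[k][e] = max(0.0, sum(params.fc2_w[e][f] * a1[f]
                                   for f in range(E)) + params.fc2_b[e])
    raw = [[0.0] * K for _ in range(N)]
    for k in range(K):
        g = []
        for a in range(A_dim):
            t = math.tanh(sum(params.attn1_w[a][e] * H[k][e]
                              for e in range(E)) + params.attn1_b[a])
            s = 1.0 / (1.0 + math.exp(-(sum(params.attn2_w[a][e] * H[k][e]
                                            for e in range(E))
                                        + params.attn2_b[a])))
            g.append(t * s)
        for i in range(N):
            raw[i][k] = sum(params.heads_w[i][a] * g[a]
                            for a in range(A_dim)) + params.heads_b[i]
    A = []
    for i in range(N):
        m = max(raw[i])
        ex = [math.exp(v - m) for v in raw[i]]
        z = sum(ex)
        A.append([v / z for v in ex])
    logits = []
    for i in range(N):
        h_slide = [sum(A[i][k] * H[k][e] for k in range(K)) for e in range(E)]
        logits.append(sum(params.clf_w[i][e] * h_slide[e] for e in range(E))
                      + params.clf_b[i])
    return np.asarray(A), np.asarray(logits)


class TestEmbed:
    def test_zero_input_zero_bias_gives_zero_row(self, tiny_params):
        p = tiny_params.copy()
        p.fc1_b[:] = 0
        p.fc2_b[:] = 0
        h = embed(np.zeros((1, p.fc1_w.shape[1])), p)
        assert np.allclose(h, 0.0)

    def test_output_nonnegative(self, tiny_params, rng):
        h = embed(rng.standard_normal((9, 10)), tiny_params)
        assert (h >= 0).all()

    def test_matches_loop_oracle(self, tiny_params, rng):
        x = rng.standard_normal((6, 10))
        h = embed(x, tiny_params)
        K, D = x.shape
        E = tiny_params.fc1_w.shape[0]
        for k in range(K):
            a1 = [max(0.0, sum(tiny_params.fc1_w[e][d] * x[k][d]
                               for d in range(D)) + tiny_params.fc1_b[e])
                  for e in range(E)]
            for e in range(E):
                expect = max(0.0, sum(tiny_params.fc2_w[e][f] * a1[f]
                                      for f in range(E)) + tiny_params.fc2_b[e])
                assert h[k][e] == pytest.approx(expect, abs=1e-6)

    def test_dim_mismatch_raises(self, tiny_params):
        with pytest.raises(ValueError):
            embed(np.zeros((3, 4)), tiny_params)


class TestAttention:
    def test_singleton_bag_attention_is_one(self, tiny_params, rng):
        a = attention_scores(rng.standard_normal((1, 8)), tiny_params)
        assert np.allclose(a, 1.0)

    def test_identical_rows_give_uniform_attention(self, tiny_params, rng):
        h = np.tile(rng.standard_normal(8), (4, 1))
        a = attention_scores(h, tiny_params)
        assert np.allclose(a, 0.25, atol=1e-12)

    def test_matches_elementwise_oracle(self, tiny_params, rng):
        x = rng.standard_normal((5, 10))
        h = embed(x, tiny_params)
        A = attention_scores(h, tiny_params)
        A_oracle, _ = loop_forward(x, tiny_params)
        assert np.abs(A - A_oracle).max() < 1e-6

    def test_rows_on_simplex(self, tiny_params, rng):
        for k in (1, 3, 40, 500):
            A = attention_scores(rng.standard_normal((k, 8)), tiny_params)
            assert (A >= 0).all()
            assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)


class TestSlideScore:
    def test_singleton_bag_representation_is_the_instance(self, tiny_params, rng):
        h = rng.standard_normal((1, 8))
        a = np.ones((3, 1))
        h_slide, _, _ = slide_score(h, a, tiny_params)
        assert np.allclose(h_slide, np.tile(h, (3, 1)))

    def test_hand_arithmetic_toy(self):
        cfg = MilConfig(n_classes=1, input_dim=2, embed_dim=2, attn_dim=2, B=1)
        p = init_params(cfg, np.random.default_rng(0))
        p.clf_w = np.array([[2.0, 4.0]])
        p.clf_b = np.array([0.0])
        h = np.array([[1.0, 0.0], [0.0, 1.0]])
        a = np.array([[0.75, 0.25]])
        _, logits, _ = slide_score(h, a, p)
        assert logits[0] == pytest.approx(2 * 0.75 + 4 * 0.25)

    def test_permutation_invariance(self, tiny_params, rng):
        x = rng.standard_normal((11, 10))
        perm = rng.permutation(11)
        r1 = forward(x, tiny_params)
        r2 = forward(x[perm], tiny_params)
        assert np.abs(r1.logits - r2.logits).max() < 1e-5
        assert np.allclose(r1.probs.sum(), 1.0, atol=1e-9)

    def test_full_forward_matches_loop_oracle(self, tiny_params, rng):
        x = rng.standard_normal((6, 10))
        res = forward(x, tiny_params)
        A_oracle, logits_oracle = loop_forward(x, tiny_params)
        assert np.abs(res.A - A_oracle).max() < 1e-6
        assert np.abs(res.logits - logits_oracle).max() < 1e-6


class TestAttentionProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(k=st.integers(1, 500), seed=st.integers(0, 2 ** 16))
    def test_attention_rows_always_on_simplex(self, k, seed):
        rng = np.random.default_rng(seed)
        cfg = MilConfig(n_classes=3, input_dim=6, embed_dim=5, attn_dim=4, B=1)
        params = init_params(cfg, rng)
        A = attention_scores(rng.standard_normal((k, 5)) * 5, params)
        assert (A >= 0).all()
        assert np.abs(A.sum(axis=1) - 1.0).max() <= 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 16))
    def test_logits_invariant_under_any_permutation(self, seed):
        rng = np.random.default_rng(seed)
        cfg = MilConfig(n_classes=3, input_dim=6, embed_dim=5, attn_dim=4, B=1)
        params = init_params(cfg, rng)
        x = rng.standard_normal((rng.integers(2, 40), 6))
        perm = rng.permutation(len(x))
        assert np.abs(forward(x, params).logits
                      - forward(x[perm], params).logits).max() <= 1e-5


class TestInstanceSelection:
    def test_two_instances(self):
        a = np.array([0.2, 0.8])
        sel = select_instances(a, B=1)
        assert sel.positive_idx.tolist() == [1]
        assert sel.negative_idx.tolist() == [0]

    def test_matches_full_sort_oracle(self, rng):
        a = rng.random(10)
        sel = select_instances(a, B=3)
        order = sorted(range(10), key=lambda i: (a[i], i))
        assert sorted(sel.negative_idx) == sorted(order[:3])
        assert sorted(sel.positive_idx) == sorted(order[-3:])

    def test_clamped_to_half_bag(self, rng):
        sel = select_instances(rng.random(3), B=8)
        assert len(sel.positive_idx) == len(sel.negative_idx) == 1

    def test_disjoint_under_ties(self):
        sel = select_instances(np.zeros(6), B=3)
        assert not set(sel.positive_idx) & set(sel.negative_idx)

    def test_tiny_bag_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            select_instances(np.array([1.0]), B=1)


class TestSmoothSvm:
    @pytest.mark.parametrize("scores,target,tau,expected", [
        ((10.0, -10.0), 0, 1.0, math.log(1 + math.exp(-19))),
        ((0.0, 0.0), 0, 1.0, math.log(1 + math.e)),
    ])
    def test_closed_form(self, scores, target, tau, expected):
        assert smooth_top1_svm_loss(np.array(scores), target, tau) == \
            pytest.approx(expected, abs=1e-9)

    def test_converges_to_hinge(self, rng):
        for _ in range(200):
            s = rng.standard_normal(2) * 3
            y = int(rng.integers(2))
            hinge = max(0.0, 1.0 + s[1 - y] - s[y])
            assert abs(smooth_top1_svm_loss(s, y, 1e-3) - hinge) <= 1e-3

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            smooth_top1_svm_loss(np.zeros(2), 0, 0.0)


class TestInstanceClusterLoss:
    def test_equal_logits_selection_independent(self, tiny_params, rng):
        p = tiny_params.copy()
        p.inst_w[:] = 0.0
        p.inst_b[:] = 0.0
        h = rng.standard_normal((7, 8))
        A = attention_scores(h, p)
        loss = instance_cluster_loss(h, A, bag_label=1, params=p, B=2)
        assert loss == pytest.approx(math.log(1 + math.e), abs=1e-9)

    def test_confident_classifier_near_zero_loss(self, tiny_config, rng):
        """An instance classifier already correct with margin > 1 on all
        2B selected patches incurs (near-)zero smooth-SVM loss."""
        p = init_params(tiny_config, rng)
        # first feature separates: attended (positive) patches have +2,
        # ignored (negative) patches -2
        h = np.zeros((6, 8))
        h[:3, 0] = 2.0
        h[3:, 0] = -2.0
        A = np.zeros((3, 6))
        A[0] = [0.3, 0.3, 0.3, 0.1 / 3, 0.1 / 3, 0.1 / 3]
        p.inst_w[0] = 0.0
        p.inst_b[0] = 0.0
        p.inst_w[0][1, 0] = 1.0   # class-1 score = +h[:,0]
        p.inst_w[0][0, 0] = -1.0  # class-0 score = -h[:,0] => margin 4
        loss = instance_cluster_loss(h, A, 0, p, B=3, tau=1e-3)
        assert loss <= 1e-3

    def test_b_clamp_uses_one_of_each(self, tiny_params, rng):
        h = rng.standard_normal((3, 8))
        A = attention_scores(h, tiny_params)
        loss = instance_cluster_loss(h, A, 0, tiny_params, B=8)
        assert np.isfinite(loss)


class TestTotalLoss:
    def test_pure_bag_loss_when_c2_zero(self):
        probs = np.array([0.2, 0.5, 0.3])
        assert total_loss(probs, 1, instance_loss=99.0, c1=1.0, c2=0.0) == \
            pytest.approx(-math.log(0.5))

    def test_perfect_prediction_zero(self):
        probs = np.array([0.0, 1.0, 0.0])
        assert total_loss(probs, 1, 0.0) == pytest.approx(0.0)

    def test_weighted_combination(self):
        probs = np.array([math.exp(-1.0), 1 - math.exp(-1.0)])
        assert total_loss(probs, 0, 2.0, c1=0.7, c2=0.3) == \
            pytest.approx(0.7 * 1.0 + 0.3 * 2.0)


class TestGradients:
    def test_finite_difference_agreement(self, rng):
        """Analytic gradients of the total loss agree with central
        differences on a random 1%+ sample of every parameter tensor."""
        cfg = MilConfig(n_classes=3, input_dim=7, embed_dim=6, attn_dim=5,
                        dropout_p=0.0, B=2)
        params = init_params(cfg, rng)
        x = rng.standard_normal((9, 7))
        y = 2
        _, grads = _forward_backward(x, y, params, cfg, rng=None, training=True)
        eps = 1e-6
        for name, arr in params.arrays().items():
            flat = arr.ravel()
            n_pick = max(1, flat.size // 100)
            for i in rng.choice(flat.size, size=min(n_pick + 3, flat.size),
                                replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = _forward_backward(x, y, params, cfg, None, True)
                flat[i] = orig - eps
                lm, _ = _forward_backward(x, y, params, cfg, None, True)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name].ravel()[i]
                assert abs(fd - g) / max(abs(fd), abs(g), 1e-6) <= 1e-3, name


class TestCheckpoint:
    def test_round_trip_bit_stable(self, tiny_config, tiny_params, tmp_path):
        path = save_checkpoint(tmp_path / "ckpt.npz", tiny_params, tiny_config)
        params2, config2 = load_checkpoint(path)
        assert config2 == tiny_config
        for k, v in tiny_params.arrays().items():
            assert np.array_equal(v, getattr(params2, k))


class TestEstimator:
    def make_data(self, rng, n=18, d=12):
        from hemamil import SyntheticBagSpec, generate_feature_bags
        spec = SyntheticBagSpec(n_classes=3, bags_per_class=n // 3,
                                bag_size_range=(10, 20),
                                evidence_fraction=0.2, feature_dim=d,
                                separation=6.0, seed=5)
        pairs = generate_feature_bags(spec)
        return ([b.features for b, _ in pairs],
                np.asarray([b.label for b, _ in pairs]))

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone
        est = GatedAttentionMIL(n_classes=3, embed_dim=16)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_training_reduces_loss_and_is_reproducible(self, rng):
        X, y = self.make_data(rng)
        kw = dict(n_classes=3, embed_dim=16, attn_dim=12, max_epochs=8,
                  patience=8, learning_rate=1e-3, random_state=7)
        est1 = GatedAttentionMIL(**kw).fit(X, y)
        est2 = GatedAttentionMIL(**kw).fit(X, y)
        assert est1.history_["train_loss"][-1] < est1.history_["train_loss"][0]
        assert est1.history_ == est2.history_
        probs = est1.predict_proba(X)
        assert probs.shape == (len(X), 3)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_encoder_is_not_part_of_training(self, rng):
        """Frozen-encoder contract: features computed before and after a
        training run are identical (the encoder never sees gradients)."""
        from hemamil.features import PooledLinearEncoder
        enc = PooledLinearEncoder(output_dim=12)
        patches = rng.integers(0, 255, size=(5, 256, 256, 3), dtype=np.uint8)
        before = enc.encode(patches)
        X, y = self.make_data(rng)
        GatedAttentionMIL(n_classes=3, embed_dim=16, attn_dim=12,
                          max_epochs=2, random_state=0).fit(X, y)
        assert np.array_equal(before, enc.encode(patches))

    def test_divergence_aborts_with_diagnostic(self, rng):
        """A non-finite training loss aborts with a diagnostic instead of
        silently optimizing garbage."""
        X, y = self.make_data(rng)
        X[0] = X[0].copy()
        X[0][0, 0] = np.nan
        est = GatedAttentionMIL(n_classes=3, embed_dim=16, attn_dim=12,
                                max_epochs=5, val_fraction=0.0,
                                random_state=0)
        with pytest.raises(FloatingPointError, match="diverged"):
            est.fit(X, y)
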