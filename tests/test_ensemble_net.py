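"""Attention-ensemble blocks, lite ensemble, gradients and checkpoints."""

import numpy as np
import pytest

from rnaensemble.ensemble_net import (
    CbamParams,
    CheckpointError,
    LiteParams,
    backward,
    channel_head,
    domain_focus_block,
    forward_cached,
    lite_backward,
    lite_combine,
    lite_forward,
    lite_softmax,
    load_checkpoint,
    rss_pattern_block,
    save_checkpoint,
    sigmoid,
    attention_forward,
)
from rnaensemble.learner_stack import LearnerStack
from rnaensemble.trainer import _bce_grad_logits, weighted_bce


def identity_params(l: int) -> CbamParams:
    """MLP = identity, centered-delta conv on the avg channel, unit head."""
    p = CbamParams.init(l)
    p.mlp_w1 = np.eye(l)
    p.mlp_b1 = np.zeros(l)
    p.mlp_w2 = np.eye(l)
    p.mlp_b2 = np.zeros(l)
    p.conv7 = np.zeros((2, 7, 7))
    p.conv_b = 0.0
    p.head_w = np.ones(l)
    p.head_b = 0.0
    return p


def random_params(l: int, seed: int = 0) -> CbamParams:
    rng = np.random.default_rng(seed)
    p = CbamParams.init(l, rng=rng)
    arrs = {k: rng.standard_normal(v.shape) * 0.3 for k, v in p.arrays().items()}
    return p.with_arrays(arrs)


def random_stack(rng, l=4, n=10) -> np.ndarray:
    A = (rng.random((l, n, n)) < 0.15).astype(float)
    A = np.triu(A, 1)
    return A + A.transpose(0, 2, 1)


class TestRssPatternBlock:
    def test_attention_strictly_inside_unit_interval(self, rng):
        Fp, _ = rss_pattern_block(random_stack(rng), random_params(4))
        assert np.all((Fp > 0) & (Fp < 1))

    def test_zero_input_zero_mlp_biases(self):
        p = identity_params(4)
        Fp, A_prime = rss_pattern_block(np.zeros((4, 8, 8)), p)
        assert np.allclose(Fp, sigmoid(0.0))
        assert np.all(A_prime == 0)

    def test_closed_form_with_identity_mlp(self):
        """A[c] constant c/10 makes avg = max = c/10, Fp[c] = sigmoid(2c/10)."""
        p = identity_params(4)
        A = np.stack([np.full((6, 6), c / 10) for c in range(4)])
        Fp, A_prime = rss_pattern_block(A, p)
        assert np.allclose(Fp, sigmoid(2 * np.arange(4) / 10), atol=1e-12)
        assert np.allclose(A_prime, Fp[:, None, None] * A, atol=1e-12)


class TestDomainFocusBlock:
    def test_attention_inside_unit_interval(self, rng):
        Fd, _ = domain_focus_block(random_stack(rng), random_params(4))
        assert Fd.shape == (10, 10)
        assert np.all((Fd > 0) & (Fd < 1))

    def test_zero_input_gives_half_attention(self):
        Fd, A_dprime = domain_focus_block(np.zeros((3, 5, 5)), identity_params(3))
        assert np.allclose(Fd, 0.5)
        assert np.all(A_dprime == 0)

    def test_centered_delta_kernel_closed_form(self, rng):
        """conv = alpha*avg + beta*max at the center tap reproduces Eq. form."""
        alpha, beta = 0.7, -0.4
        p = identity_params(1)
        p.conv7[0, 3, 3] = alpha
        p.conv7[1, 3, 3] = beta
        A = random_stack(rng, l=1, n=9)
        Fd, _ = domain_focus_block(A, p)
        expected = sigmoid(alpha * A.mean(axis=0) + beta * A.max(axis=0))
        assert np.allclose(Fd, expected, atol=1e-12)


class TestChannelHead:
    def test_one_hot_head_on_binary_input(self, rng):
        p = identity_params(4)
        p.head_w = np.array([1.0, 0, 0, 0])
        A = random_stack(rng)
        Y = channel_head(A, p)
        assert set(np.unique(Y)) <= {sigmoid(0.0), sigmoid(1.0)}

    def test_shape_and_range(self, rng):
        Y = channel_head(random_stack(rng, n=7), random_params(4))
        assert Y.shape == (7, 7)
        assert np.all((Y > 0) & (Y < 1))

    def test_zero_input_constant_bias(self):
        p = identity_params(2)
        p.head_b = -1.3
        assert np.allclose(channel_head(np.zeros((2, 4, 4)), p), sigmoid(-1.3))


class TestAttentionForward:
    def test_pure_function(self, rng):
        A = random_stack(rng)
        p = random_params(4)
        assert np.array_equal(attention_forward(A, p), attention_forward(A, p))

    def test_permutation_invariance(self, rng):
        """Permuting learners with correspondingly permuted params fixes Y."""
        A = random_stack(rng)
        p = random_params(4, seed=5)
        perm = np.array([2, 0, 3, 1])
        p2 = random_params(4, seed=5)
        p2.mlp_w1 = p.mlp_w1[:, perm][perm, :]
        p2.mlp_b1 = p.mlp_b1[perm]
        p2.mlp_w2 = p.mlp_w2[:, perm][perm, :]
        p2.mlp_b2 = p.mlp_b2[perm]
        p2.head_w = p.head_w[perm]
        Y1 = attention_forward(A, p)
        Y2 = attention_forward(A[perm], p2)
        assert np.allclose(Y1, Y2, atol=1e-12)

    def test_reduces_to_vote_count_without_attention(self, rng):
        """Unit head on raw stack = sigmoid of the per-cell learner vote."""
        A = random_stack(rng, l=3, n=5)
        p = identity_params(3)
        Y = channel_head(A, p)
        votes = A.sum(axis=0)  # hand vote-counting oracle
        assert np.allclose(Y, sigmoid(votes), atol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        A = random_stack(rng, n=9)
        Z = np.zeros((9, 9))
        Z[0, 5] = Z[5, 0] = 1.0
        p = random_params(4, seed=7)
        cache = forward_cached(A, p)
        grads = backward(cache, _bce_grad_logits(cache["Y"], Z, None, 300.0), p)
        eps = 1e-6
        for key, arr in p.arrays().items():
            arr = np.atleast_1d(arr)
            gk = np.atleast_1d(grads[key]).ravel()
            for idx in rng.choice(arr.size, size=min(5, arr.size), replace=False):
                shift = {k: np.atleast_1d(v).astype(float).copy() for k, v in p.arrays().items()}
                shift[key].ravel()[idx] += eps
                up = weighted_bce(forward_cached(A, p.with_arrays(shift))["Y"], Z, None, 300.0)
                shift[key].ravel()[idx] -= 2 * eps
                down = weighted_bce(forward_cached(A, p.with_arrays(shift))["Y"], Z, None, 300.0)
                fd = (up - down) / (2 * eps)
                assert abs(fd - gk[idx]) <= 1e-4 * max(1.0, abs(fd))


class TestLite:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ((0.0, 0.0, 0.0, 0.0), (0.25, 0.25, 0.25, 0.25)),
            ((1000.0, 0.0), (1.0, 0.0)),
        ],
    )
    def test_softmax_values(self, raw, expected):
        pi = lite_softmax(np.array(raw))
        assert np.all(np.isfinite(pi))
        assert np.allclose(pi, expected, atol=1e-12)

    def test_softmax_normalized(self, rng):
        for _ in range(20):
            pi = lite_softmax(rng.standard_normal(6) * 10)
            assert abs(pi.sum() - 1.0) < 1e-12

    def test_combine_identity_and_agreement(self, rng):
        A = random_stack(rng, l=2, n=8)
        assert np.array_equal(lite_combine(A, np.array([1.0, 0.0])), A[0])
        agree = np.zeros((2, 8, 8))
        agree[:, 0, 6] = agree[:, 6, 0] = 1.0
        Y = lite_combine(agree, np.array([0.5, 0.5]))
        assert Y[0, 6] == 1.0

    def test_combine_weighted_entry(self):
        A = np.zeros((3, 10, 10))
        for v in (0, 2):  # pair present in learners 0 and 2 only
            A[v, 1, 7] = A[v, 7, 1] = 1.0
        Y = lite_combine(A, np.array([0.2, 0.3, 0.5]))
        assert Y[1, 7] == pytest.approx(0.7, abs=1e-12)

    def test_combine_monotone_in_weight(self, rng):
        A = random_stack(rng, l=3)
        cell = tuple(np.argwhere(A[0] > 0)[0])
        raw = np.zeros(3)
        y_before = lite_forward(A, LiteParams(raw))[cell]
        y_after = lite_forward(A, LiteParams(raw + np.array([2.0, 0, 0])))[cell]
        assert y_after >= y_before

    def test_lite_gradient_matches_finite_differences(self, rng):
        A = random_stack(rng, l=4, n=8)
        Z = np.zeros((8, 8))
        Z[0, 5] = Z[5, 0] = 1.0
        p = LiteParams(rng.standard_normal(4))
        from rnaensemble.trainer import weighted_bce_grad

        dY = weighted_bce_grad(lite_forward(A, p), Z, None, 300.0)
        g = lite_backward(A, p, dY)["raw_weights"]
        eps = 1e-6
        for v in range(4):
            shift = p.raw_weights.copy()
            shift[v] += eps
            up = weighted_bce(lite_forward(A, LiteParams(shift)), Z, None, 300.0)
            shift[v] -= 2 * eps
            down = weighted_bce(lite_forward(A, LiteParams(shift)), Z, None, 300.0)
            assert abs((up - down) / (2 * eps) - g[v]) < 1e-4


class TestCheckpoints:
    def test_round_trip_both_kinds(self, tmp_path, rng):
        names = ("a", "b", "c", "d")
        for params in (random_params(4), LiteParams(rng.standard_normal(4))):
            path = tmp_path / "ck.json"
            save_checkpoint(path, params, names, seed=3)
            loaded, meta = load_checkpoint(path, expected_learner_names=names)
            assert meta["seed"] == 3
            for k, v in params.arrays().items():
                assert np.allclose(np.atleast_1d(loaded.arrays()[k]), np.atleast_1d(v))

    def test_learner_order_mismatch_refused(self, tmp_path):
        path = tmp_path / "ck.json"
        save_checkpoint(path, LiteParams.init(2), ("a", "b"))
        with pytest.raises(CheckpointError, match="order"):
            load_checkpoint(path, expected_learner_names=("b", "a"))
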