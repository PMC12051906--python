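"""Loss oracles: every alignment loss is checked against an independent
brute-force implementation of its defining formula on tiny instances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msalign import (
    LossWeights,
    cross_entropy,
    kd_loss,
    mcc_loss,
    mmd_loss,
    msa_total_loss,
)

# ----------------------------------------------------------------------
# independent reference implementations (plain loops, no shared code path)
# ----------------------------------------------------------------------

def softmax_ref(z):
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def kd_ref(student, teacher, tau):
    ps = softmax_ref(np.asarray(student) / tau)
    pt = softmax_ref(np.asarray(teacher) / tau)
    kl = 0.0
    for b in range(len(ps)):
        for k in range(ps.shape[1]):
            kl += pt[b, k] * (np.log(pt[b, k]) - np.log(ps[b, k]))
    return kl / len(ps) * tau ** 2


def mmd_ref(xs, xt, gamma):
    def k(a, b):
        return np.exp(-gamma * np.sum((a - b) ** 2))
    n, m = len(xs), len(xt)
    kss = sum(k(a, b) for a in xs for b in xs) / n ** 2
    ktt = sum(k(a, b) for a in xt for b in xt) / m ** 2
    kst = sum(k(a, b) for a in xs for b in xt) / (n * m)
    return kss + ktt - 2 * kst


def mcc_ref(logits, tau):
    Y = softmax_ref(np.asarray(logits) / tau)
    B, K = Y.shape
    H = -np.sum(Y * np.log(Y), axis=1)
    w = 1.0 + np.exp(-H)
    w = B * w / w.sum()
    C = Y.T @ np.diag(w) @ Y
    C = C / C.sum(axis=1, keepdims=True)
    return (C.sum() - np.trace(C)) / K


class TestKDLoss:
    def test_zero_when_student_equals_teacher(self, rng):
        z = rng.standard_normal((4, 3))
        assert kd_loss(z, z.copy(), tau=2.0) == pytest.approx(0.0, abs=1e-9)

    def test_binary_closed_form(self):
        # teacher (2,0), student (0,0), tau=1: KL(Bernoulli(sigma(2)) || Bernoulli(0.5))
        p = 1.0 / (1.0 + np.exp(-2.0))
        expected = p * np.log(p / 0.5) + (1 - p) * np.log((1 - p) / 0.5)
        got = kd_loss(np.array([[0.0, 0.0]]), np.array([[2.0, 0.0]]), tau=1.0)
        assert got == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("tau", [1.0, 2.0, 4.0])
    def test_matches_bruteforce_reference(self, rng, tau):
        s = rng.standard_normal((6, 4))
        t = rng.standard_normal((6, 4))
        assert kd_loss(s, t, tau) == pytest.approx(kd_ref(s, t, tau), abs=1e-5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative_gibbs_inequality(self, seed):
        r = np.random.default_rng(seed)
        s, t = r.standard_normal((3, 3)) * 5, r.standard_normal((3, 3)) * 5
        assert kd_loss(s, t, tau=2.0) >= -1e-7

    def test_decreases_as_student_approaches_teacher(self):
        teacher = np.array([[3.0, -1.0]])
        vals = [kd_loss(np.array([[3.0 * a, -1.0 * a]]), teacher, tau=1.0)
                for a in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            kd_loss(np.zeros((2, 1)), np.zeros((2, 1)), tau=1.0)


class TestMMDLoss:
    def test_zero_for_identical_samples(self, rng):
        x = rng.standard_normal((8, 5))
        assert mmd_loss(x, x.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_kernel_sum(self):
        # n=m=2, F=1, single kernel with fixed bandwidth 1
        xs = np.array([[0.0], [1.0]])
        xt = np.array([[2.0], [3.0]])
        got = mmd_loss(xs, xt, bandwidth_multipliers=(1.0,), base_bandwidth=1.0)
        assert got == pytest.approx(mmd_ref(xs, xt, gamma=1.0), abs=1e-9)

    def test_multikernel_matches_reference(self, rng):
        xs = rng.standard_normal((5, 3))
        xt = rng.standard_normal((6, 3)) + 1.0
        mults = (0.25, 0.5, 1.0, 2.0, 4.0)
        base = 2.0
        got = mmd_loss(xs, xt, bandwidth_multipliers=mults, base_bandwidth=base)
        expected = np.mean([mmd_ref(xs, xt, gamma=1.0 / (m * base)) for m in mults])
        assert got == pytest.approx(expected, abs=1e-6)

    def test_symmetric_in_arguments(self, rng):
        xs, xt = rng.standard_normal((4, 2)), rng.standard_normal((5, 2))
        assert mmd_loss(xs, xt) == pytest.approx(mmd_loss(xt, xs), abs=1e-7)

    def test_separated_distributions_exceed_null(self):
        # N(0,1) vs N(3,1) beats the same-distribution value in >=95/100 draws
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a, b = r.standard_normal((64, 1)), r.standard_normal((64, 1))
            null = mmd_loss(a, b)
            alt = mmd_loss(a, r.standard_normal((64, 1)) + 3.0)
            hits += alt > null
        assert hits >= 95

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            mmd_loss(rng.standard_normal((1, 2)), rng.standard_normal((4, 2)))


class TestMCCLoss:
    def test_one_hot_logits_give_zero_confusion(self, rng):
        logits = np.array([[20.0, -20.0], [-20.0, 20.0], [20.0, -20.0],
                           [-20.0, 20.0]])
        assert mcc_loss(logits, tau=1.0) <= 1e-6

    def test_uniform_logits_match_stepwise_reference(self):
        logits = np.zeros((4, 2))
        assert mcc_loss(logits, tau=2.5) == pytest.approx(
            mcc_ref(logits, 2.5), abs=1e-7)

    @pytest.mark.parametrize("tau", [1.0, 2.5])
    def test_matches_stepwise_reference_random(self, rng, tau):
        logits = rng.standard_normal((8, 3)) * 2
        assert mcc_loss(logits, tau) == pytest.approx(
            mcc_ref(logits, tau), abs=1e-5)

    def test_class_permutation_invariance(self, rng):
        logits = rng.standard_normal((6, 4))
        perm = [2, 0, 3, 1]
        assert mcc_loss(logits, 2.5) == pytest.approx(
            mcc_loss(logits[:, perm], 2.5), abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 5))
    def test_bounded_by_class_count(self, seed, K):
        r = np.random.default_rng(seed)
        logits = r.standard_normal((6, K)) * 3
        val = mcc_loss(logits, tau=2.5)
        assert -1e-7 <= val <= (K - 1) / K + 1e-7

    def test_single_example_rejected(self):
        with pytest.raises(ValueError):
            mcc_loss(np.zeros((1, 2)), tau=1.0)


class TestCompositionAndCE:
    def test_cross_entropy_closed_form_single_example(self):
        logits = np.array([[1.0, 3.0]])
        p_true = np.exp(3.0) / (np.exp(1.0) + np.exp(3.0))
        assert cross_entropy(logits, [1]) == pytest.approx(-np.log(p_true),
                                                           abs=1e-6)

    def test_total_reduces_to_ce_with_zero_weights(self):
        w = LossWeights(lambda_kd=0.0, beta_da=0.0)
        assert msa_total_loss(1.7, 5.0, 9.0, w) == pytest.approx(1.7, abs=1e-12)

    def test_total_default_weights_are_unit(self):
        w = LossWeights()
        assert w.lambda_kd == 1.0 and w.beta_da == 1.0
        assert msa_total_loss(1.0, 2.0, 3.0, w) == pytest.approx(6.0, abs=1e-12)

    def test_total_arithmetic(self):
        w = LossWeights(lambda_kd=0.5, beta_da=2.0)
        assert msa_total_loss(1.0, 2.0, 3.0, w) == pytest.approx(8.0, abs=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_kd=-1.0)
        with pytest.raises(ValueError):
            LossWeights(tau_kd=0.0)


class TestTensorArrayConsistency:
    """The float32 training-graph route and the float64 array route of each
    loss implement the same formula."""

    def test_all_losses_agree_across_routes(self, rng):
        from msalign.nn import Tensor

        s = rng.standard_normal((6, 3)).astype(np.float32)
        t = rng.standard_normal((6, 3)).astype(np.float32)
        f1 = rng.standard_normal((5, 4)).astype(np.float32)
        f2 = (rng.standard_normal((7, 4)) + 1).astype(np.float32)
        y = rng.integers(0, 3, 6)
        pairs = [
            (kd_loss(Tensor(s), Tensor(t), 2.0).item(), kd_loss(s, t, 2.0)),
            (mcc_loss(Tensor(s), 2.5).item(), mcc_loss(s, 2.5)),
            (mmd_loss(Tensor(f1), Tensor(f2)).item(), mmd_loss(f1, f2)),
            (cross_entropy(Tensor(s), y).item(), cross_entropy(s, y)),
        ]
        for graph_val, array_val in pairs:
            assert graph_val == pytest.approx(array_val, abs=2e-5)
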