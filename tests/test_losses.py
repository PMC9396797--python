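import math

import numpy as np
import pytest

from rnapairnet.autograd import Tensor
from rnapairnet.losses import (
    LossConfig,
    get_loss,
    matrix_inner,
    negative_f1_loss,
    pr_auc_loss,
    soft_precision,
    soft_recall,
    weighted_logistic_loss,
)


def loop_inner(x, y):
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            total += x[i, j] * y[i, j]
    return total


def loop_pr_auc(x, y, steps, eps=1e-8):
    """Independent explicit-loop trapezoid sweep of the soft P-R curve."""
    pts = []
    for k in range(steps, -1, -1):
        t = k / steps
        tp = fp = fn = 0.0
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                d = max(x[i, j] - t, 0.0)
                tp += d * y[i, j]
                fp += d * (1 - y[i, j])
                fn += (1 - d) * y[i, j]
        pts.append((tp / (tp + fn + eps), tp / (tp + fp + eps)))
    total = 0.0
    for (r0, p0), (r1, p1) in zip(pts[:-1], pts[1:]):
        total += (r1 - r0) * (p0 + p1)
    return -0.5 * total


class TestInnerAndSoftMetrics:
    def test_identity_inner(self):
        assert matrix_inner(np.eye(3), np.eye(3)) == 3.0

    def test_zero_inner(self):
        assert matrix_inner(np.zeros((4, 4)), np.ones((4, 4))) == 0.0

    def test_inner_matches_loop(self, rng):
        x, y = rng.normal(size=(5, 5)), rng.normal(size=(5, 5))
        assert matrix_inner(x, y) == pytest.approx(loop_inner(x, y))

    def test_perfect_and_inverted_predictions(self, rng):
        y = (rng.random((6, 6)) < 0.3).astype(float)
        y.flat[0] = 1.0
        assert soft_precision(y, y) == pytest.approx(1.0, abs=1e-6)
        assert soft_recall(y, y) == pytest.approx(1.0, abs=1e-6)
        assert soft_precision(1 - y, y) == pytest.approx(0.0, abs=1e-6)
        assert soft_recall(np.zeros_like(y), y) == pytest.approx(0.0, abs=1e-6)

    def test_binary_inputs_match_count_oracle(self, rng):
        for _ in range(1000):
            x = (rng.random((6, 6)) < 0.4).astype(float)
            y = (rng.random((6, 6)) < 0.4).astype(float)
            tp = np.sum((x == 1) & (y == 1))
            fp = np.sum((x == 1) & (y == 0))
            fn = np.sum((x == 0) & (y == 1))
            p_expected = tp / (tp + fp) if tp + fp else 0.0
            r_expected = tp / (tp + fn) if tp + fn else 0.0
            assert soft_precision(x, y) == pytest.approx(p_expected, abs=1e-6)
            assert soft_recall(x, y) == pytest.approx(r_expected, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_precision(np.zeros((2, 2)), np.zeros((3, 3)))


class TestWeightedLogistic:
    def test_analytic_single_elements(self):
        assert weighted_logistic_loss(np.array([[0.0]]), np.array([[0.0]])) == pytest.approx(math.log(2))
        assert weighted_logistic_loss(np.array([[0.0]]), np.array([[1.0]]), pw=256) == pytest.approx(256 * math.log(2))

    def test_saturation(self):
        assert weighted_logistic_loss(np.array([[40.0]]), np.array([[1.0]])) == pytest.approx(0.0, abs=1e-10)

    def test_pw_one_equals_plain_bce(self, rng):
        x = rng.normal(size=(8, 8))
        y = (rng.random((8, 8)) < 0.3).astype(float)
        sig = 1 / (1 + np.exp(-x))
        bce = np.mean(-y * np.log(sig) - (1 - y) * np.log(1 - sig))
        assert weighted_logistic_loss(x, y, pw=1.0) == pytest.approx(bce, rel=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            weighted_logistic_loss(np.array([[np.inf]]), np.array([[1.0]]))


class TestNegativeF1:
    def test_range_and_endpoints(self, rng):
        y = (rng.random((6, 6)) < 0.3).astype(float)
        y.flat[0] = 1.0
        assert negative_f1_loss(y, y) == pytest.approx(-1.0, abs=1e-6)
        assert negative_f1_loss(1 - y, y) == pytest.approx(0.0, abs=1e-6)
        assert negative_f1_loss(np.zeros_like(y), np.zeros_like(y)) == 0.0

    def test_binary_matches_count_oracle(self, rng):
        for _ in range(200):
            x = (rng.random((6, 6)) < 0.4).astype(float)
            y = (rng.random((6, 6)) < 0.4).astype(float)
            tp = np.sum((x == 1) & (y == 1))
            fp = np.sum((x == 1) & (y == 0))
            fn = np.sum((x == 0) & (y == 1))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * p * r / (p + r) if p + r else 0.0
            assert negative_f1_loss(x, y) == pytest.approx(-f1, abs=1e-5)


class TestPrAucLoss:
    def test_matches_explicit_loop_oracle(self, rng):
        for _ in range(5):
            x = rng.random((5, 5))
            y = (rng.random((5, 5)) < 0.4).astype(float)
            assert pr_auc_loss(x, y, steps=20) == pytest.approx(loop_pr_auc(x, y, 20), abs=1e-10)

    def test_constant_half_scores_match_oracle(self, rng):
        x = np.full((6, 6), 0.5)
        y = (rng.random((6, 6)) < 0.3).astype(float)
        assert pr_auc_loss(x, y, steps=50) == pytest.approx(loop_pr_auc(x, y, 50), abs=1e-10)

    def test_perfect_separation_approaches_minus_one(self, rng):
        y = (rng.random((8, 8)) < 0.3).astype(float)
        y.flat[0] = 1.0
        assert pr_auc_loss(y, y, steps=100) == pytest.approx(-1.0, abs=0.02)

    def test_permutation_invariance(self, rng):
        x = rng.random((5, 5))
        y = (rng.random((5, 5)) < 0.4).astype(float)
        perm = rng.permutation(25)
        xp = x.flat[perm].reshape(5, 5)
        yp = y.flat[perm].reshape(5, 5)
        assert pr_auc_loss(x, y, steps=30) == pytest.approx(pr_auc_loss(xp, yp, steps=30), abs=1e-12)

    def test_range(self, rng):
        x = rng.random((6, 6))
        y = (rng.random((6, 6)) < 0.4).astype(float)
        val = pr_auc_loss(x, y, steps=30)
        assert -1.0 - 1e-6 <= val <= 1e-3


class TestGradients:
    @pytest.mark.parametrize("loss_name", ["weighted_logistic", "negative_f1", "pr_auc"])
    def test_finite_difference_gradient(self, loss_name, rng):
        cfg = LossConfig(name=loss_name, pw=4.0, auc_steps=10)
        fn = get_loss(cfg)
        x0 = rng.random((4, 4)) * 0.8 + 0.05
        if loss_name == "weighted_logistic":
            x0 = rng.normal(size=(4, 4))
        y = (rng.random((4, 4)) < 0.4).astype(float)
        xt = Tensor(x0, requires_grad=True)
        out = fn(xt, Tensor(y))
        out.backward()
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (3, 3)]:
            xp, xm = x0.copy(), x0.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (fn(xp, y) - fn(xm, y)) / (2 * eps)
            assert xt.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestLossConfig:
    @pytest.mark.parametrize("kwargs", [{"pw": 0}, {"auc_steps": 1}, {"epsilon": 0}])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LossConfig(**kwargs)

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError):
            get_loss(LossConfig(name="hinge"))
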