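import numpy as np
import pytest

from rnapairnet.autograd import Tensor
from rnapairnet.constraint_layer import (
    ConstraintLayerConfig,
    OptState,
    binarize,
    denoise,
    finalize,
    grad_A,
    postprocess,
    update_A,
    update_lambda,
)
from rnapairnet.constraints import build_constraint_matrix, validate_structure
from rnapairnet.io import structure_to_pair_matrix
from rnapairnet.synthetic import SyntheticConfig, assign_sequence, generate_dataset, generate_structure

from conftest import oracle_logits


def make_state(A, lam=None, t=1):
    n = A.shape[0]
    return OptState(A=Tensor(A), lam=Tensor(lam if lam is not None else np.zeros(n)), t=t)


class TestGradA:
    def test_feasible_rows_reduce_to_score_term(self, rng):
        A = rng.random((5, 5)) * 0.1  # all row sums < 1
        S, y = rng.random((5, 5)), (rng.random((5, 5)) < 0.3).astype(float)
        g = grad_A(make_state(A, lam=rng.random(5)), S, y, b=0.5).data
        assert np.allclose(g, S - 0.5 + y)

    def test_zero_gradient_at_threshold_scores(self):
        S = np.full((4, 4), 0.5)
        g = grad_A(make_state(np.zeros((4, 4))), S, np.zeros((4, 4)), b=0.5).data
        assert np.allclose(g, 0.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        n = 6
        A = rng.random((n, n))
        lam = rng.random(n)
        S, y, b = rng.random((n, n)), (rng.random((n, n)) < 0.3).astype(float), 0.4
        got = grad_A(make_state(A, lam=lam), S, y, b).data
        rowsum = A.sum(axis=1)
        for i in range(n):
            for j in range(n):
                pen = lam[i] if rowsum[i] - 1 > 0 else 0.0
                assert got[i, j] == pytest.approx(S[i, j] - b + y[i, j] - pen)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            grad_A(make_state(np.zeros((3, 3))), np.zeros((3, 3)), np.zeros((4, 4)), 0.5)


class TestUpdateA:
    def test_zero_matrix_is_fixed_point(self, rng):
        cfg = ConstraintLayerConfig()
        st = make_state(np.zeros((4, 4)))
        g = Tensor(rng.normal(size=(4, 4)))
        assert not update_A(st, g, np.ones((4, 4)), cfg).A.data.any()

    def test_masked_entries_stay_zero(self, rng):
        cfg = ConstraintLayerConfig()
        M = (rng.random((5, 5)) < 0.5).astype(float)
        st = make_state(rng.random((5, 5)) * M)
        g = Tensor(rng.normal(size=(5, 5)))
        out = update_A(st, g, M, cfg).A.data
        assert not out[M == 0].any()

    def test_symmetry_preserved(self, rng):
        cfg = ConstraintLayerConfig()
        A = rng.random((5, 5))
        A = (A + A.T) / 2
        M = np.ones((5, 5))
        G = rng.normal(size=(5, 5))
        G = (G + G.T) / 2
        out = update_A(make_state(A), Tensor(G), M, cfg).A.data
        assert np.allclose(out, out.T)

    def test_iterate_stays_in_unit_interval(self, rng):
        cfg = ConstraintLayerConfig()
        out = update_A(make_state(rng.random((5, 5))), Tensor(rng.normal(size=(5, 5)) * 10),
                       np.ones((5, 5)), cfg).A.data
        assert (out >= 0).all() and (out <= 1).all()


class TestLambdaAndDenoise:
    def test_lambda_unchanged_when_feasible(self):
        cfg = ConstraintLayerConfig()
        st = make_state(np.eye(4) * 0.5, lam=np.ones(4))
        assert np.allclose(update_lambda(st, cfg).lam.data, np.ones(4))

    def test_lambda_grows_by_scaled_excess(self):
        cfg = ConstraintLayerConfig()
        A = np.zeros((4, 4))
        A[0] = 0.5  # row sum 2
        st = make_state(A, t=3)
        out = update_lambda(st, cfg).lam.data
        assert out[0] == pytest.approx(cfg.rho_beta**3 * 1.0)
        assert not out[1:].any()

    def test_lambda_nondecreasing_over_random_trajectory(self, rng):
        cfg = ConstraintLayerConfig()
        st = make_state(rng.random((6, 6)), t=1)
        prev = st.lam.data.copy()
        for t in range(1, 10):
            st.t = t
            st = update_A(st, grad_A(st, rng.random((6, 6)), np.zeros((6, 6)), 0.5),
                          np.ones((6, 6)), cfg)
            st = denoise(st, cfg)
            st = update_lambda(st, cfg)
            assert (st.lam.data >= prev - 1e-12).all()
            prev = st.lam.data.copy()

    def test_denoise_shrinks_and_zeroes(self):
        cfg = ConstraintLayerConfig(eta=0.01)
        A = np.array([[0.0, 0.9], [0.005, 0.011]])
        out = denoise(make_state(A, t=0), cfg).A.data
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(0.89)
        assert out[1, 0] == 0.0  # |A| <= eta * rho^0
        assert out[1, 1] == pytest.approx(0.001)


class TestFinalize:
    def test_symmetric_input_unchanged_up_to_mask(self, rng):
        A = rng.random((5, 5))
        A = (A + A.T) / 2
        M = (rng.random((5, 5)) < 0.6).astype(float)
        M = np.maximum(M, M.T)
        out = finalize(make_state(A), M).data
        assert np.allclose(out, A * M)

    def test_asymmetric_input_half_sum(self, rng):
        A = rng.random((4, 4))
        M = np.ones((4, 4))
        out = finalize(make_state(A), M).data
        assert np.allclose(out, (A + A.T) / 2)


class TestBinarize:
    def test_disjoint_high_entries_kept(self):
        A = np.zeros((8, 8))
        A[0, 5] = A[5, 0] = 0.9
        A[1, 6] = A[6, 1] = 0.8
        out = binarize(A, 0.5)
        assert out[0, 5] == out[1, 6] == 1 and out.sum() == 4

    def test_conflicts_resolved_by_score(self):
        A = np.zeros((8, 8))
        A[0, 5] = A[5, 0] = 0.9
        A[0, 6] = A[6, 0] = 0.8
        out = binarize(A, 0.5)
        assert out[0, 5] == 1 and out[0, 6] == 0

    def test_ties_broken_lexicographically(self):
        A = np.zeros((8, 8))
        A[0, 5] = A[5, 0] = 0.9
        A[0, 4] = A[4, 0] = 0.9
        out = binarize(A, 0.5)
        assert out[0, 4] == 1 and out[0, 5] == 0


class TestPostprocess:
    def test_single_planted_pair_recovered(self):
        n = 12
        M = np.ones((n, n)) - np.eye(n)
        S = np.full((n, n), -6.0)
        S[2, 9] = S[9, 2] = 6.0
        _, hard = postprocess(S, M)
        expected = np.zeros((n, n))
        expected[2, 9] = expected[9, 2] = 1
        assert np.array_equal(hard, expected)

    def test_all_negative_scores_give_empty_structure(self):
        n = 10
        _, hard = postprocess(np.full((n, n), -8.0), np.ones((n, n)) - np.eye(n))
        assert not hard.any()

    def test_planted_structures_recovered_including_pseudoknots(self, small_corpus):
        n_exact = 0
        for seq, structure in small_corpus:
            label = structure_to_pair_matrix(structure)
            mask = build_constraint_matrix(seq)
            _, hard = postprocess(oracle_logits(label), mask)
            n_exact += int(np.array_equal(hard, label))
        assert n_exact == len(small_corpus)

    def test_hard_output_always_satisfies_rules(self, rng):
        for _ in range(200):
            length = int(rng.integers(10, 50))
            structure = generate_structure(length, 0.3, 0.3, rng)
            seq = assign_sequence(structure, rng)
            mask = build_constraint_matrix(seq)
            _, hard = postprocess(rng.normal(0, 3, size=(length, length)), mask)
            assert validate_structure(hard, mask) == []

    def test_differentiable_with_respect_to_scores(self, planted_case, rng):
        # probe an imperfect operating point: with oracle scores the iterate
        # saturates at the clamp bounds and the (sub)gradient is legitimately zero
        seq, structure, label, mask = planted_case
        S = Tensor(rng.normal(0, 1, size=label.shape), requires_grad=True)
        soft, _ = postprocess(S, mask, y=label, cfg=ConstraintLayerConfig(s=5))
        from rnapairnet.losses import negative_f1_loss

        loss = negative_f1_loss(soft, Tensor(label.astype(float)))
        loss.backward()
        assert S.grad is not None and np.isfinite(S.grad).all()
        assert np.abs(S.grad).sum() > 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            postprocess(np.zeros((4, 4)), np.zeros((5, 5)))

    @pytest.mark.parametrize("kwargs", [{"rho_alpha": 1.0}, {"rho_beta": 0.0}, {"s": 0}, {"eta": -1}])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConstraintLayerConfig(**kwargs)
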