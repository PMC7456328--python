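import numpy as np
import pytest

from adrml.factorization import (
    HyperParams,
    fit,
    gradient_hessian_P,
    gradient_hessian_Q,
    loss,
    predict_dual,
    update_P,
    update_Q,
)
from adrml.io import ResponseMatrix, SimilarityMatrix
from conftest import random_raw_similarity, random_response


def identity_sim(ids):
    return SimilarityMatrix(list(ids), np.eye(len(ids)))


def make_instance(seed, n=8, m=5, k=3, missing=0.2):
    """Random masked instance with raw nonnegative similarities (PD regime)."""
    rng = np.random.default_rng(seed)
    R = random_response(rng, n, m, missing)
    simC = random_raw_similarity(rng, R.cell_ids)
    simD = random_raw_similarity(rng, R.drug_ids)
    P = rng.standard_normal((n, k))
    Q = rng.standard_normal((m, k))
    return R, simC, simD, P, Q


class TestLoss:
    def test_exact_reconstruction_zero(self):
        R = ResponseMatrix(["c"], ["d"], [[1.0]], [[True]])
        assert loss(R, np.array([[1.0]]), np.array([[1.0]]), np.eye(1), np.eye(1), 0, 0) == 0.0

    def test_hand_value_with_ridge(self):
        R = ResponseMatrix(["c"], ["d"], [[2.0]], [[True]])
        value = loss(R, np.array([[1.0]]), np.array([[1.0]]), np.eye(1), np.eye(1), 2.0, 0.0)
        assert value == pytest.approx(2.5)  # 0.5*(2-1)^2 + 1*(1+1)

    def test_identical_rows_kill_manifold_term(self):
        R, simC, simD, P, Q = make_instance(0)
        P[:] = P[0]
        Q[:] = Q[0]
        base = loss(R, P, Q, simC, simD, 0.0, 0.0)
        with_lam = loss(R, P, Q, simC, simD, 0.0, 5.0)
        assert with_lam == pytest.approx(base)

    def test_masked_entries_excluded(self):
        values = np.array([[1.0, np.nan]])
        R = ResponseMatrix(["c"], ["d1", "d2"], values, [[True, False]])
        P, Q = np.array([[1.0]]), np.array([[1.0], [100.0]])
        assert loss(R, P, Q, np.eye(1), np.eye(2), 0, 0) == 0.0

    def test_manifold_term_bruteforce(self):
        R, simC, simD, P, Q = make_instance(3)
        lam = 1.7
        expected = 0.0
        for i in range(P.shape[0]):
            for j in range(P.shape[0]):
                expected += np.sum((P[i] - P[j]) ** 2) * simC.values[i, j]
        for i in range(Q.shape[0]):
            for j in range(Q.shape[0]):
                expected += np.sum((Q[i] - Q[j]) ** 2) * simD.values[i, j]
        expected *= lam / 2
        got = loss(R, P, Q, simC, simD, 0.0, lam) - loss(R, P, Q, simC, simD, 0.0, 0.0)
        assert got == pytest.approx(expected, rel=1e-10)


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_finite_difference_P(self, seed):
        R, simC, simD, P, Q = make_instance(seed)
        mu, lam, delta = 0.7, 1.3, 1e-6
        for i in (0, 3):
            grad, _ = gradient_hessian_P(i, R, P, Q, simC, mu, lam)
            for h in range(P.shape[1]):
                Pp, Pm = P.copy(), P.copy()
                Pp[i, h] += delta
                Pm[i, h] -= delta
                numeric = (
                    loss(R, Pp, Q, simC, simD, mu, lam) - loss(R, Pm, Q, simC, simD, mu, lam)
                ) / (2 * delta)
                assert grad[h] == pytest.approx(numeric, rel=1e-5, abs=1e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_finite_difference_Q(self, seed):
        R, simC, simD, P, Q = make_instance(seed + 10)
        mu, lam, delta = 0.7, 1.3, 1e-6
        for j in (0, 2):
            grad, _ = gradient_hessian_Q(j, R, P, Q, simD, mu, lam)
            for h in range(Q.shape[1]):
                Qp, Qm = Q.copy(), Q.copy()
                Qp[j, h] += delta
                Qm[j, h] -= delta
                numeric = (
                    loss(R, P, Qp, simC, simD, mu, lam) - loss(R, P, Qm, simC, simD, mu, lam)
                ) / (2 * delta)
                assert grad[h] == pytest.approx(numeric, rel=1e-5, abs=1e-5)

    def test_hessian_reduces_to_ridge_gram(self):
        R, simC, simD, P, Q = make_instance(4, missing=0.0)
        mu = 2.5
        _, hess = gradient_hessian_P(1, R, P, Q, simC, mu, 0.0)
        assert np.allclose(hess, Q.T @ Q + mu * np.eye(Q.shape[1]))

    def test_gradient_vanishes_at_row_minimizer(self):
        R, simC, simD, P, Q = make_instance(5)
        newP = update_P(R, P, Q, simC, 0.9, 1.1)
        # the last row's subproblem was solved against the final state
        grad, _ = gradient_hessian_P(P.shape[0] - 1, R, newP, Q, simC, 0.9, 1.1)
        assert np.linalg.norm(grad) < 1e-8


class TestUpdates:
    def test_lam_zero_is_ridge_least_squares(self):
        R, simC, simD, P, Q = make_instance(6, missing=0.0)
        mu = 1.5
        newP = update_P(R, P, Q, simC, mu, 0.0)
        expected = R.values @ Q @ np.linalg.inv(Q.T @ Q + mu * np.eye(Q.shape[1]))
        assert np.allclose(newP, expected)
        newQ = update_Q(R, newP, Q, simD, mu, 0.0)
        expected_q = R.values.T @ newP @ np.linalg.inv(
            newP.T @ newP + mu * np.eye(newP.shape[1])
        )
        assert np.allclose(newQ, expected_q)

    @pytest.mark.parametrize("seed", range(100))
    def test_derived_update_never_increases_loss(self, seed):
        R, simC, simD, P, Q = make_instance(seed, n=7, m=5, k=2)
        mu, lam = 0.5, 0.8
        before = loss(R, P, Q, simC, simD, mu, lam)
        P2 = update_P(R, P, Q, simC, mu, lam)
        mid = loss(R, P2, Q, simC, simD, mu, lam)
        Q2 = update_Q(R, P2, Q, simD, mu, lam)
        after = loss(R, P2, Q2, simC, simD, mu, lam)
        assert mid <= before + 1e-10 * abs(before)
        assert after <= mid + 1e-10 * abs(mid)

    def test_update_from_optimum_is_fixed_point(self):
        R, simC, simD, _, _ = make_instance(7, n=6, m=4, k=2)
        hyper = HyperParams(
            k_percent=50, mu=0.5, lam=0.5, epsilon=1e-12, max_iter=3000,
            seed=0, use_normalized_similarity=False,
        )
        factors = fit(R, simC, simD, hyper)
        newP = update_P(R, factors.P, factors.Q, simC, 0.5, 0.5)
        assert np.linalg.norm(newP - factors.P) < 1e-6

    def test_as_printed_variant_differs_but_runs(self):
        R, simC, simD, P, Q = make_instance(8)
        derived = update_P(R, P, Q, simC, 1.0, 1.0, "derived")
        printed = update_P(R, P, Q, simC, 1.0, 1.0, "as_printed")
        assert not np.allclose(derived, printed)


class TestFit:
    def test_rank_one_recovery(self):
        R = ResponseMatrix(["c1", "c2"], ["d1", "d2"], [[1.0, 2.0], [2.0, 4.0]], np.ones((2, 2), bool))
        hyper = HyperParams(
            k_percent=50, mu=1e-6, lam=0.0, epsilon=1e-9, max_iter=2000, seed=1,
            use_normalized_similarity=False,
        )
        factors = fit(R, identity_sim(R.cell_ids), identity_sim(R.drug_ids), hyper)
        assert np.linalg.norm(R.values - factors.predict()) < 1e-3

    def test_exact_factorization_regime(self):
        rng = np.random.default_rng(9)
        R = random_response(rng, 6, 4, missing=0.0)
        hyper = HyperParams(
            k_percent=100, mu=0.0, lam=0.0, epsilon=1e-10, max_iter=5000, seed=2,
            use_normalized_similarity=False,
        )
        factors = fit(R, identity_sim(R.cell_ids), identity_sim(R.drug_ids), hyper)
        rel = np.linalg.norm(R.values - factors.predict()) / np.linalg.norm(R.values)
        assert rel < 1e-6

    def test_loss_trace_monotone_under_derived_updates(self):
        R, simC, simD, _, _ = make_instance(10, n=12, m=6)
        hyper = HyperParams(k_percent=40, mu=1.0, lam=1.0, seed=3, use_normalized_similarity=False)
        factors = fit(R, simC, simD, hyper)
        trace = np.array(factors.loss_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_block_gradients_small_at_convergence(self):
        R, simC, simD, _, _ = make_instance(11, n=10, m=6)
        hyper = HyperParams(
            k_percent=40, mu=1.0, lam=1.0, epsilon=1e-10, max_iter=5000, seed=4,
            use_normalized_similarity=False,
        )
        factors = fit(R, simC, simD, hyper)
        k = factors.P.shape[1]
        scale = np.sqrt(k) * max(1.0, np.abs(R.values[R.observed_mask]).max())
        for i in range(R.n_cells):
            grad, _ = gradient_hessian_P(i, R, factors.P, factors.Q, simC, 1.0, 1.0)
            assert np.linalg.norm(grad) < 1e-4 * scale
        for j in range(R.n_drugs):
            grad, _ = gradient_hessian_Q(j, R, factors.P, factors.Q, simD, 1.0, 1.0)
            assert np.linalg.norm(grad) < 1e-4 * scale

    def test_same_seed_bit_identical(self):
        R, simC, simD, _, _ = make_instance(12)
        hyper = HyperParams(k_percent=40, mu=1.0, lam=0.5, seed=5, use_normalized_similarity=False)
        a = fit(R, simC, simD, hyper)
        b = fit(R, simC, simD, hyper)
        assert np.array_equal(a.P, b.P) and np.array_equal(a.Q, b.Q)
        assert a.loss_trace == b.loss_trace

    def test_transpose_symmetry(self):
        R, simC, simD, _, _ = make_instance(13, n=6, m=6, k=2)
        hyper = HyperParams(
            k_percent=40, mu=1.0, lam=0.7, epsilon=1e-10, max_iter=2000, seed=6,
            use_normalized_similarity=False,
        )
        rng = np.random.default_rng(99)
        k = hyper.latent_dim(6, 6)
        P0 = rng.random((6, k))
        Q0 = rng.random((6, k))
        forward = fit(R, simC, simD, hyper, init=(P0, Q0))
        Rt = ResponseMatrix(
            list(R.drug_ids), list(R.cell_ids), R.values.T.copy(), R.observed_mask.T.copy()
        )
        # swapping roles and the warm start must transpose the solution;
        # note the alternating order then optimizes Q0's side first, so
        # compare the converged predictions rather than raw factors
        backward = fit(Rt, simD, simC, hyper, init=(Q0, P0))
        assert np.allclose(forward.predict(), backward.predict().T, atol=1e-6)

    def test_misaligned_labels_error(self):
        R, simC, simD, _, _ = make_instance(14)
        wrong = SimilarityMatrix(["zz" + c for c in R.cell_ids], simC.values)
        with pytest.raises(KeyError):
            fit(R, wrong, simD, HyperParams(use_normalized_similarity=False))


class TestPredictDual:
    def test_combined_is_mean(self):
        R, simC, simD, _, _ = make_instance(15)
        hyper = HyperParams(k_percent=40, mu=1.0, lam=0.5, seed=7, use_normalized_similarity=False)
        result = predict_dual(R, simC, simD, hyper)
        assert np.allclose(result.combined, 0.5 * (result.forward + result.reverse))

    def test_defined_for_unobserved_entries(self):
        R, simC, simD, _, _ = make_instance(16, missing=0.3)
        hyper = HyperParams(k_percent=40, mu=1.0, lam=0.5, seed=8, use_normalized_similarity=False)
        result = predict_dual(R, simC, simD, hyper)
        assert np.all(np.isfinite(result.combined))

    def test_averaging_rarely_hurts_heldout_rmse(self):
        hits = 0
        trials = 100
        for seed in range(trials):
            rng = np.random.default_rng(1000 + seed)
            truthP = rng.standard_normal((12, 2))
            truthQ = rng.standard_normal((5, 2))
            clean = truthP @ truthQ.T
            mask = rng.random((12, 5)) >= 0.25
            values = np.where(mask, clean + 0.05 * rng.standard_normal((12, 5)), np.nan)
            R = ResponseMatrix(
                [f"c{i}" for i in range(12)], [f"d{j}" for j in range(5)], values, mask
            )
            simC = random_raw_similarity(rng, R.cell_ids)
            simD = random_raw_similarity(rng, R.drug_ids)
            hyper = HyperParams(
                k_percent=40, mu=0.1, lam=0.05, seed=seed, use_normalized_similarity=False
            )
            result = predict_dual(R, simC, simD, hyper)
            held = ~mask

            def rmse_of(pred):
                return float(np.sqrt(np.mean((clean[held] - pred[held]) ** 2)))

            if rmse_of(result.combined) <= max(
                rmse_of(result.forward), rmse_of(result.reverse)
            ) + 1e-9:
                hits += 1
        assert hits >= 0.9 * trials

    def test_heldout_recovery_noiseless(self):
        rng = np.random.default_rng(17)
        truthP = rng.standard_normal((40, 3))
        truthQ = rng.standard_normal((10, 3))
        clean = truthP @ truthQ.T
        mask = rng.random((40, 10)) >= 0.2
        values = np.where(mask, clean, np.nan)
        R = ResponseMatrix(
            [f"c{i}" for i in range(40)], [f"d{j}" for j in range(10)], values, mask
        )
        simC = random_raw_similarity(rng, R.cell_ids)
        simD = random_raw_similarity(rng, R.drug_ids)
        hyper = HyperParams(
            k_percent=30, mu=0.01, lam=0.0, seed=9, epsilon=1e-6, max_iter=2000,
            use_normalized_similarity=False,
        )
        result = predict_dual(R, simC, simD, hyper)
        held = ~mask
        corr = np.corrcoef(clean[held], result.combined[held])[0, 1]
        assert corr > 0.95
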