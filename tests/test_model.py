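"""Objective, gradients, fitting, smoothing and prediction.

The analytic gradients are checked against central finite differences of
the log-likelihood, and the full fit is checked against an independently
coded plain logistic matrix factorization in the reduction case
(beta = gamma = 0, c = 1).
"""

import numpy as np
import pytest

from dnilmf.model import (
    Hyperparams,
    fit,
    gradients,
    interaction_probability,
    linear_predictor,
    load_model,
    log_likelihood,
    predict,
    predict_pairs,
    save_model,
    smooth_new_entities,
)
from conftest import random_similarity


def _random_instance(rng, n_d, n_t, r):
    Y = (rng.random((n_d, n_t)) < 0.3).astype(float)
    U = rng.standard_normal((n_d, r)) * 0.3
    V = rng.standard_normal((n_t, r)) * 0.3
    S_d = random_similarity(rng, n_d)
    S_t = random_similarity(rng, n_t)
    return Y, U, V, S_d, S_t


class TestLinearPredictor:
    def test_reduces_to_plain_mf(self, rng):
        _, U, V, S_d, S_t = _random_instance(rng, 4, 3, 2)
        np.testing.assert_allclose(
            linear_predictor(U, V, S_d, S_t, 1.0, 0.0, 0.0), U @ V.T
        )

    def test_zero_latents_give_zero(self, rng):
        _, U, V, S_d, S_t = _random_instance(rng, 4, 3, 2)
        x = linear_predictor(np.zeros_like(U), V, S_d, S_t, 0.5, 0.25, 0.25)
        np.testing.assert_array_equal(x, 0.0)

    def test_matches_triple_loop(self, rng):
        Y, U, V, S_d, S_t = _random_instance(rng, 4, 3, 2)
        a, b, g = 0.5, 0.25, 0.25
        x = linear_predictor(U, V, S_d, S_t, a, b, g)
        UVt = np.array(
            [[sum(U[i, k] * V[j, k] for k in range(2)) for j in range(3)]
             for i in range(4)]
        )
        expected = np.zeros((4, 3))
        for i in range(4):
            for j in range(3):
                s_term = sum(S_d[i, u] * UVt[u, j] for u in range(4))
                t_term = sum(UVt[i, v] * S_t[v, j] for v in range(3))
                expected[i, j] = a * UVt[i, j] + b * s_term + g * t_term
        np.testing.assert_allclose(x, expected, atol=1e-12)


class TestInteractionProbability:
    def test_midpoint_and_saturation(self):
        x = np.array([0.0, 800.0, -800.0])
        p = interaction_probability(x)
        assert p[0] == 0.5
        assert p[1] == 1.0
        assert p[2] == 0.0

    def test_symmetry(self, rng):
        x = rng.standard_normal(100) * 10
        p = interaction_probability(x)
        np.testing.assert_allclose(p + interaction_probability(-x), 1.0, atol=1e-12)


class TestLogLikelihood:
    def test_zero_latents_closed_form(self, rng):
        for _ in range(5):
            n_d, n_t = rng.integers(2, 9, size=2)
            Y = (rng.random((n_d, n_t)) < 0.3).astype(float)
            U = np.zeros((n_d, 2))
            V = np.zeros((n_t, 2))
            ll = log_likelihood(Y, np.zeros((n_d, n_t)), 1.0, 0.0, 0.0, U, V)
            assert ll == pytest.approx(-n_d * n_t * np.log(2.0), abs=1e-10)

    def test_matches_scalar_loop(self, rng):
        Y, U, V, S_d, S_t = _random_instance(rng, 6, 5, 3)
        x = linear_predictor(U, V, S_d, S_t, 0.5, 0.25, 0.25)
        c, lu, lv = 5.0, 5.0, 1.0
        ll = log_likelihood(Y, x, c, lu, lv, U, V)
        expected = 0.0
        for i in range(6):
            for j in range(5):
                w = 1.0 + c * Y[i, j] - Y[i, j]
                expected += c * Y[i, j] * x[i, j] - w * np.log1p(np.exp(x[i, j]))
        expected -= 0.5 * lu * (U**2).sum() + 0.5 * lv * (V**2).sum()
        assert ll == pytest.approx(expected, abs=1e-10)


class TestGradients:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(42)
        hyper = Hyperparams(num_latent=3)
        step = 1e-6
        worst = 0.0
        for _ in range(20):
            n_d, n_t = rng.integers(3, 9, size=2)
            r = int(rng.integers(2, 5))
            Y, U, V, S_d, S_t = _random_instance(rng, n_d, n_t, r)

            def ll(Uv, Vv):
                x = linear_predictor(Uv, Vv, S_d, S_t, hyper.alpha, hyper.beta,
                                     hyper.gamma)
                return log_likelihood(Y, x, hyper.c, hyper.lambda_u,
                                      hyper.lambda_v, Uv, Vv)

            dU, dV = gradients(Y, U, V, S_d, S_t, hyper)
            num_dU = np.zeros_like(U)
            for i in range(U.shape[0]):
                for k in range(U.shape[1]):
                    Up, Um = U.copy(), U.copy()
                    Up[i, k] += step
                    Um[i, k] -= step
                    num_dU[i, k] = (ll(Up, V) - ll(Um, V)) / (2 * step)
            num_dV = np.zeros_like(V)
            for j in range(V.shape[0]):
                for k in range(V.shape[1]):
                    Vp, Vm = V.copy(), V.copy()
                    Vp[j, k] += step
                    Vm[j, k] -= step
                    num_dV[j, k] = (ll(U, Vp) - ll(U, Vm)) / (2 * step)
            scale_u = np.maximum(np.abs(num_dU), 1.0)
            scale_v = np.maximum(np.abs(num_dV), 1.0)
            worst = max(
                worst,
                np.max(np.abs(dU - num_dU) / scale_u),
                np.max(np.abs(dV - num_dV) / scale_v),
            )
        assert worst <= 1e-5

    def test_stationary_point_with_zero_penalty(self, rng):
        # at U = V = 0 with lambda = 0 every gradient term carries a
        # factor of U or V, so the ascent direction vanishes exactly
        n_d, n_t, r = 4, 3, 2
        Y = (rng.random((n_d, n_t)) < 0.5).astype(float)
        hyper = Hyperparams(num_latent=r, c=1.0, lambda_u=0.0, lambda_v=0.0)
        U = np.zeros((n_d, r))
        V = np.zeros((n_t, r))
        dU, dV = gradients(Y, U, V, np.eye(n_d), np.eye(n_t), hyper)
        np.testing.assert_array_equal(dU, 0.0)
        np.testing.assert_array_equal(dV, 0.0)

    def test_reduction_to_plain_lmf_gradients(self, rng):
        Y, U, V, S_d, S_t = _random_instance(rng, 5, 4, 2)
        hyper = Hyperparams(num_latent=2, alpha=1.0, beta=0.0, gamma=0.0, c=1.0,
                            lambda_u=2.0, lambda_v=3.0)
        dU, dV = gradients(Y, U, V, S_d, S_t, hyper)
        P = 1.0 / (1.0 + np.exp(-(U @ V.T)))
        Q = Y - P
        np.testing.assert_allclose(dU, Q @ V - 2.0 * U, atol=1e-12)
        np.testing.assert_allclose(dV, Q.T @ U - 3.0 * V, atol=1e-12)


def plain_logistic_mf(Y, r, lam_u, lam_v, lr, n_iter, seed):
    """Independent plain logistic MF with AdaGrad, coded from scratch.

    Tracks the update rule of the full model only through its published
    recipe: Q = Y - sigmoid(UV'), dU = QV - lam_u U, dV = Q'U - lam_v V,
    AdaGrad with accumulator starting at zero and eps inside the root.
    """
    rng = np.random.default_rng(seed)
    n_d, n_t = Y.shape
    U = rng.standard_normal((n_d, r)) / np.sqrt(r)
    V = rng.standard_normal((n_t, r)) / np.sqrt(r)
    G_u = np.zeros_like(U)
    G_v = np.zeros_like(V)
    trace = []
    for _ in range(n_iter):
        P = 1.0 / (1.0 + np.exp(-(U @ V.T)))
        Q = Y - P
        dU = Q @ V - lam_u * U
        dV = Q.T @ U - lam_v * V
        G_u += dU**2
        G_v += dV**2
        U = U + lr * dU / np.sqrt(G_u + 1e-8)
        V = V + lr * dV / np.sqrt(G_v + 1e-8)
        x = U @ V.T
        ll = np.sum(Y * x - np.logaddexp(0.0, x))
        ll -= 0.5 * lam_u * (U**2).sum() + 0.5 * lam_v * (V**2).sum()
        trace.append(ll)
    return U, V, trace


class TestFit:
    def test_deterministic_given_seed(self, rng):
        Y = (rng.random((10, 8)) < 0.3).astype(float)
        S_d = random_similarity(rng, 10)
        S_t = random_similarity(rng, 8)
        h = Hyperparams(num_latent=4, max_iter=20, seed=3)
        m1 = fit(Y, S_d, S_t, h)
        m2 = fit(Y, S_d, S_t, h)
        np.testing.assert_array_equal(m1.U, m2.U)
        np.testing.assert_array_equal(m1.V, m2.V)

    def test_objective_improves(self, small_synthetic):
        ds, _ = small_synthetic
        h = Hyperparams(num_latent=5, max_iter=40, seed=1)
        S_d = np.eye(ds.n_drugs)
        S_t = np.eye(ds.n_targets)
        m = fit(ds.Y, S_d, S_t, h)
        assert m.ll_trace[-1] > m.ll_trace[0]
        assert len(m.ll_trace) == 40

    def test_reduction_matches_plain_lmf_per_iteration(self, rng):
        Y = (rng.random((30, 20)) < 0.2).astype(float)
        h = Hyperparams(num_latent=3, alpha=1.0, beta=0.0, gamma=0.0, c=1.0,
                        lambda_u=0.5, lambda_v=0.5, learn_rate=0.1,
                        max_iter=50, seed=9)
        m = fit(Y, np.eye(30), np.eye(20), h)
        U, V, trace = plain_logistic_mf(Y, 3, 0.5, 0.5, 0.1, 50, 9)
        np.testing.assert_allclose(m.U, U, atol=1e-10)
        np.testing.assert_allclose(m.V, V, atol=1e-10)
        np.testing.assert_allclose(m.ll_trace, trace, atol=1e-10)

    def test_huge_penalty_shrinks_latents(self, rng):
        Y = (rng.random((12, 10)) < 0.3).astype(float)
        h = Hyperparams(num_latent=3, lambda_u=1e6, lambda_v=1e6, max_iter=60,
                        seed=2)
        S_d = random_similarity(rng, 12)
        S_t = random_similarity(rng, 10)
        m = fit(Y, S_d, S_t, h)
        init = np.random.default_rng(2)
        U0 = init.standard_normal((12, 3)) / np.sqrt(3)
        V0 = init.standard_normal((10, 3)) / np.sqrt(3)
        assert np.linalg.norm(m.U) < np.linalg.norm(U0)
        assert np.linalg.norm(m.V) < np.linalg.norm(V0)
        P = predict(m)
        assert np.abs(P - 0.5).max() < 0.05


class TestSmoothing:
    def _fitted(self, rng, n_d=8, n_t=6):
        Y = (rng.random((n_d, n_t)) < 0.4).astype(float)
        S_d = random_similarity(rng, n_d)
        S_t = random_similarity(rng, n_t)
        return fit(Y, S_d, S_t, Hyperparams(num_latent=3, max_iter=5, seed=0))

    def test_single_neighbor_copies_row(self, rng):
        m = self._fitted(rng)
        m.hyper.k_smooth = 1
        sm = smooth_new_entities(m, {0}, set())
        known = np.arange(1, 8)
        best = known[np.argmax(m.S_d[0, known])]
        np.testing.assert_allclose(sm.U[0], m.U[best])

    def test_weighted_mean_scalar_loop(self, rng):
        m = self._fitted(rng)
        m.hyper.k_smooth = 3
        sm = smooth_new_entities(m, {2}, set())
        known = np.array([i for i in range(8) if i != 2])
        order = np.argsort(-m.S_d[2, known], kind="stable")[:3]
        nbrs = known[order]
        expected = np.zeros(3)
        total = 0.0
        for u in nbrs:
            expected += m.S_d[2, u] * m.U[u]
            total += m.S_d[2, u]
        np.testing.assert_allclose(sm.U[2], expected / total, atol=1e-12)

    def test_convex_combination_bounds(self, rng):
        m = self._fitted(rng)
        sm = smooth_new_entities(m, {1, 4}, {0})
        known_d = [i for i in range(8) if i not in (1, 4)]
        for i in (1, 4):
            lo = m.U[known_d].min(axis=0) - 1e-12
            hi = m.U[known_d].max(axis=0) + 1e-12
            assert ((sm.U[i] >= lo) & (sm.U[i] <= hi)).all()

    def test_untouched_rows_identical(self, rng):
        m = self._fitted(rng)
        sm = smooth_new_entities(m, {0}, set())
        np.testing.assert_array_equal(sm.U[1:], m.U[1:])
        np.testing.assert_array_equal(sm.V, m.V)

    def test_unfitted_model_rejected(self, rng):
        m = self._fitted(rng)
        m.fitted = False
        with pytest.raises(RuntimeError):
            smooth_new_entities(m, set(), set())


class TestPredict:
    def test_scores_in_unit_interval_and_ranking(self, rng):
        Y = (rng.random((6, 5)) < 0.3).astype(float)
        S_d = random_similarity(rng, 6)
        S_t = random_similarity(rng, 5)
        m = fit(Y, S_d, S_t, Hyperparams(num_latent=2, max_iter=10, seed=1))
        P = predict(m)
        assert (P > 0).all() and (P < 1).all()
        pairs = [(i, j) for i in range(6) for j in range(5)]
        table = predict_pairs(m, pairs, [f"D{i}" for i in range(6)],
                              [f"T{j}" for j in range(5)], Y)
        scores = [r["score"] for r in table.records]
        assert scores == sorted(scores, reverse=True)

    def test_zero_latent_model_scores_half(self):
        from dnilmf.model import DNILMFModel
        m = DNILMFModel(U=np.zeros((3, 2)), V=np.zeros((4, 2)),
                        S_d=np.eye(3), S_t=np.eye(4),
                        hyper=Hyperparams(num_latent=2), fitted=True)
        np.testing.assert_array_equal(predict(m), 0.5)

    def test_unfitted_predict_rejected(self):
        from dnilmf.model import DNILMFModel
        m = DNILMFModel(U=np.zeros((3, 2)), V=np.zeros((4, 2)),
                        S_d=np.eye(3), S_t=np.eye(4),
                        hyper=Hyperparams(num_latent=2), fitted=False)
        with pytest.raises(RuntimeError):
            predict(m)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        Y = (rng.random((5, 4)) < 0.4).astype(float)
        m = fit(Y, random_similarity(rng, 5), random_similarity(rng, 4),
                Hyperparams(num_latent=2, max_iter=5, seed=4))
        path = str(tmp_path / "model.npz")
        save_model(m, path, drug_ids=list("abcde"), target_ids=list("wxyz"))
        back, meta = load_model(path)
        np.testing.assert_array_equal(back.U, m.U)
        np.testing.assert_array_equal(back.S_t, m.S_t)
        assert back.hyper == m.hyper
        assert meta["drug_ids"] == list("abcde")
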