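"""Block updates, penalty rule and the full alternating solver."""

import numpy as np
import pytest

from tglrr.graph import build_graph, graph_penalty
from tglrr.prox import soft_threshold, svt, top_r_factors
from tglrr.solver import (
    TGLRRParams,
    TGLRRState,
    fit_tglrr,
    objective_value,
    singular_value_curve,
    suggest_r,
    update_F,
    update_G,
    update_P,
    update_mu,
    update_multipliers,
    update_Z,
)


def make_state(rng, m, n, mu=1.0, zero=False):
    def draw(shape):
        return np.zeros(shape) if zero else rng.normal(size=shape)

    return TGLRRState(
        Z=draw((n, n)), G=draw((m, m)), F=draw((n, n)), P=draw((m, n)),
        Y1=draw((m, n)), Y2=draw((n, n)), mu=mu, iter=1,
    )


class TestObjective:
    def test_zero_state(self):
        params = TGLRRParams(r=1)
        assert objective_value(
            np.zeros((3, 4)), np.zeros((4, 4)), np.zeros((3, 3)),
            np.zeros((3, 4)), np.zeros((4, 4)), params,
        ) == pytest.approx(0.0)

    def test_reduces_to_plain_nuclear_objective(self, rng):
        """r=0, beta=0 leaves nuclear norms of Z and G plus the L1 term."""
        Z, G, P = rng.normal(size=(4, 4)), rng.normal(size=(3, 3)), rng.normal(size=(3, 4))
        params = TGLRRParams(lam=0.3, beta=0.0, r=0)
        expected = (
            np.linalg.svd(Z, compute_uv=False).sum()
            + np.linalg.svd(G, compute_uv=False).sum()
            + 0.3 * np.abs(P).sum()
        )
        got = objective_value(rng.normal(size=(3, 4)), Z, G, P, np.zeros((4, 4)), params)
        assert got == pytest.approx(expected)

    def test_term_by_term_oracle(self, rng):
        X = rng.normal(size=(5, 6))
        Z, G, P = rng.normal(size=(6, 6)), rng.normal(size=(5, 5)), rng.normal(size=(5, 6))
        L = build_graph(X, 2).L
        params = TGLRRParams(lam=0.7, beta=1.3, r=2)
        s_z = np.linalg.svd(Z, compute_uv=False)
        expected = (
            s_z[2:].sum()
            + np.linalg.svd(G, compute_uv=False).sum()
            + 0.5 * 1.3 * graph_penalty(Z, L)
            + 0.7 * np.abs(P).sum()
        )
        assert objective_value(X, Z, G, P, L, params) == pytest.approx(expected)


class TestBlockUpdates:
    def test_update_Z_stationary_input_is_pure_svt(self, rng):
        """With zero gradient the step reduces to SVT of Z_k."""
        m, n = 3, 4
        state = make_state(rng, m, n, mu=2.0, zero=True)
        state.Z = rng.normal(size=(n, n))
        state.F = state.Z.copy()  # Y2 = 0 so Z - F + Y2/mu = 0
        X = np.zeros((m, n))
        L = np.zeros((n, n))
        params = TGLRRParams(beta=0.5, r=0)
        eta1 = 2.0 * (1.0 + 0.0)  # beta*||L|| + mu*(1 + ||X||^2)
        expected = svt(state.Z, 1.0 / (eta1 * 2.0))
        got = update_Z(state, X, L, top_r_factors(state.Z, 0), params)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_update_Z_scalar_closed_form(self):
        """1x1 problem matches the hand-derived scalar prox formula."""
        state = TGLRRState(
            Z=np.array([[2.0]]), G=np.array([[0.5]]), F=np.array([[1.0]]),
            P=np.array([[0.2]]), Y1=np.array([[0.3]]), Y2=np.array([[-0.1]]),
            mu=1.5, iter=1,
        )
        X = np.array([[2.0]])
        L = np.array([[0.0]])
        params = TGLRRParams(beta=0.0, r=0)
        mu, x = 1.5, 2.0
        eta1 = mu * (1 + x**2)
        grad = mu * (2.0 - 1.0 + (-0.1) / mu) + mu * x * (
            x * 2.0 - x + 0.5 * x + 0.2 - 0.3 / mu
        )
        arg = 2.0 - grad / eta1
        expected = np.sign(arg) * max(abs(arg) - 1.0 / (eta1 * mu), 0.0)
        got = update_Z(state, X, L, top_r_factors(state.Z, 0), params)
        assert got[0, 0] == pytest.approx(expected)

    def test_update_Z_decreases_prox_surrogate(self, rng):
        """The proximal objective of the linearized subproblem never
        increases at the returned point."""
        m, n = 5, 6
        state = make_state(rng, m, n, mu=1.2)
        X = rng.normal(size=(m, n))
        L = build_graph(X, 2).L
        params = TGLRRParams(beta=0.8, r=2)
        mu = state.mu
        eta1 = 0.8 * np.linalg.norm(L, 2) + mu * (1 + np.linalg.norm(X, 2) ** 2)
        resid = X @ state.Z - X + state.G @ X + state.P - state.Y1 / mu
        grad = 0.8 * state.Z @ L + mu * (state.Z - state.F + state.Y2 / mu) + mu * X.T @ resid
        target = state.Z - grad / eta1

        def prox_obj(Z):
            return (1.0 / (eta1 * mu)) * np.linalg.svd(Z, compute_uv=False).sum() \
                + 0.5 * np.sum((Z - target) ** 2)

        Z_new = update_Z(state, X, L, top_r_factors(state.Z, 2), params)
        assert prox_obj(Z_new) <= prox_obj(state.Z) + 1e-10

    def test_update_G_zero_gradient_is_pure_svt(self, rng):
        """Zero residual and Y1 = 0 reduce the G step to SVT of G_k."""
        m, n = 3, 4
        state = make_state(rng, m, n, mu=2.0, zero=True)
        state.G = rng.normal(size=(m, m))
        X = rng.normal(size=(m, n))
        Z_new = np.zeros((n, n))
        state.P = X - X @ Z_new - state.G @ X  # makes the residual vanish
        eta2 = 2.0 * np.linalg.norm(X, 2) ** 2
        expected = svt(state.G, 1.0 / (eta2 * 2.0))
        got = update_G(state, X, Z_new, TGLRRParams())
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_update_G_gradient_support_pattern(self, rng):
        """With a single nonzero column in X the gradient lives on the
        corresponding outer-product pattern."""
        m, n = 4, 5
        X = np.zeros((m, n))
        X[:, 2] = rng.normal(size=m)
        state = make_state(rng, m, n, mu=1.0, zero=True)
        state.P = rng.normal(size=(m, n))
        Z_new = np.zeros((n, n))
        mu = state.mu
        grad_expected = mu * (X @ Z_new - X + state.G @ X + state.P - state.Y1 / mu) @ X.T
        # gradient is (stuff) @ X.T: columns of X.T are zero except row 2
        manual = mu * np.outer((X @ Z_new - X + state.G @ X + state.P)[:, 2], X[:, 2])
        np.testing.assert_allclose(grad_expected, manual, atol=1e-12)
        eta2 = mu * np.linalg.norm(X, 2) ** 2
        expected = svt(state.G - grad_expected / eta2, 1.0 / (eta2 * mu))
        np.testing.assert_allclose(update_G(state, X, Z_new, TGLRRParams()), expected)

    def test_update_F_empty_factors(self, rng):
        state = make_state(rng, 3, 4, mu=2.0)
        Z_new = rng.normal(size=(4, 4))
        fp = top_r_factors(Z_new, 0)
        np.testing.assert_allclose(
            update_F(state, Z_new, fp, TGLRRParams(r=0)),
            Z_new + state.Y2 / 2.0,
        )

    def test_update_F_is_stationary_point(self, rng):
        """Finite-difference gradient of the F subproblem vanishes at the
        returned point."""
        n = 5
        state = make_state(rng, 3, n, mu=1.7)
        Z_new = rng.normal(size=(n, n))
        fp = top_r_factors(Z_new, 2)
        F_star = update_F(state, Z_new, fp, TGLRRParams(r=2))

        def f_obj(F):
            return (
                -np.trace(fp.A @ F @ fp.B.T)
                + np.sum(state.Y2 * (Z_new - F))
                + 0.5 * state.mu * np.sum((Z_new - F) ** 2)
            )

        h = 1e-6
        for _ in range(5):
            i, j = np.random.default_rng(0).integers(0, n, 2)
            E = np.zeros((n, n))
            E[i, j] = h
            num_grad = (f_obj(F_star + E) - f_obj(F_star - E)) / (2 * h)
            assert num_grad == pytest.approx(0.0, abs=1e-6)

    def test_update_F_large_mu_limit(self, rng):
        state = make_state(rng, 3, 4, mu=1e12, zero=True)
        Z_new = rng.normal(size=(4, 4))
        fp = top_r_factors(Z_new, 2)
        np.testing.assert_allclose(
            update_F(state, Z_new, fp, TGLRRParams(r=2)), Z_new, atol=1e-10
        )

    def test_update_P_zero_lambda_identity(self, rng):
        m, n = 3, 4
        state = make_state(rng, m, n, mu=1.0)
        X = rng.normal(size=(m, n))
        Z_new, G_new = rng.normal(size=(n, n)), rng.normal(size=(m, m))
        arg = X - X @ Z_new - G_new @ X + state.Y1 / state.mu
        np.testing.assert_allclose(
            update_P(state, X, Z_new, G_new, TGLRRParams(lam=0.0)), arg
        )

    def test_update_P_entrywise_prox_oracle(self, rng):
        """Each entry minimizes lam|p| + mu/2 (p - a)^2, checked by grid search."""
        m, n = 2, 3
        state = make_state(rng, m, n, mu=2.0)
        X = rng.normal(size=(m, n))
        Z_new, G_new = rng.normal(size=(n, n)), rng.normal(size=(m, m))
        params = TGLRRParams(lam=0.6)
        P = update_P(state, X, Z_new, G_new, params)
        arg = X - X @ Z_new - G_new @ X + state.Y1 / state.mu
        grid = np.linspace(-20, 20, 800001)
        for i in range(m):
            for j in range(n):
                vals = 0.6 * np.abs(grid) + 0.5 * 2.0 * (grid - arg[i, j]) ** 2
                assert P[i, j] == pytest.approx(grid[np.argmin(vals)], abs=1e-4)

    def test_multipliers_definitional(self, rng):
        m, n = 3, 4
        state = make_state(rng, m, n, mu=1.0)
        X = rng.normal(size=(m, n))
        Y1, Y2 = update_multipliers(state, X, mu_new=2.5)
        np.testing.assert_allclose(
            Y1, state.Y1 + 2.5 * (X - X @ state.Z - state.G @ X - state.P)
        )
        np.testing.assert_allclose(Y2, state.Y2 + 2.5 * (state.Z - state.F))

    def test_multipliers_unchanged_at_feasibility(self, rng):
        m, n = 3, 4
        state = make_state(rng, m, n, mu=1.0, zero=True)
        X = np.zeros((m, n))
        Y1, Y2 = update_multipliers(state, X, mu_new=5.0)
        np.testing.assert_array_equal(Y1, state.Y1)
        np.testing.assert_array_equal(Y2, state.Y2)


class TestPenaltyRule:
    def test_grows_when_settled(self):
        p = TGLRRParams(mu0=1.0, mu_max=100.0, rho0=1.5, eps2=1.0)
        assert update_mu(2.0, changes=0.4, params=p) == pytest.approx(3.0)

    def test_frozen_when_still_moving(self):
        p = TGLRRParams(mu0=1.0, mu_max=100.0, rho0=1.5, eps2=1.0)
        assert update_mu(2.0, changes=10.0, params=p) == pytest.approx(2.0)

    def test_capped_at_mu_max(self):
        p = TGLRRParams(mu0=1.0, mu_max=5.0, rho0=2.0, eps2=1e9)
        assert update_mu(5.0, changes=0.0, params=p) == pytest.approx(5.0)


class TestRSelection:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((100, 90, 5, 4, 3), 2),
            ((10, 1, 1, 1), 1),
            ((5, 2), 1),
        ],
    )
    def test_known_curves(self, values, expected):
        assert suggest_r(np.array(values, dtype=float)) == expected

    def test_geometric_decay_gives_one(self):
        s = 10.0 * 0.5 ** np.arange(15)
        assert suggest_r(s) == 1

    def test_singular_value_curve(self, rng):
        np.testing.assert_allclose(
            singular_value_curve(np.diag([5.0, 2.0, 1.0])), [5.0, 2.0, 1.0]
        )
        M = rng.normal(size=(6, 4))
        np.testing.assert_allclose(
            singular_value_curve(M), np.linalg.svd(M, compute_uv=False)
        )


class TestFit:
    def test_zero_matrix_fixed_point(self):
        res = fit_tglrr(np.zeros((4, 5)), TGLRRParams(max_iter=10))
        assert res.converged and res.n_iter == 1
        np.testing.assert_array_equal(res.Z_star, np.zeros((5, 5)))
        np.testing.assert_array_equal(res.G_star, np.zeros((4, 4)))
        np.testing.assert_array_equal(res.P_star, np.zeros((4, 5)))
        assert res.history[0]["objective"] == pytest.approx(0.0)

    def test_feasibility_on_synthetic_fixture(self, small_fixture, small_fit):
        res = small_fit
        X = small_fixture.X.values
        assert res.converged
        feas = np.linalg.norm(
            X - X @ res.Z_star - res.G_star @ X - res.P_star
        ) / np.linalg.norm(X)
        assert feas <= 1e-6 * 1.01

    def test_deterministic_history(self, small_fixture):
        p = TGLRRParams(max_iter=40)
        r1 = fit_tglrr(small_fixture.X, p)
        r2 = fit_tglrr(small_fixture.X, p)
        assert r1.history == r2.history
        np.testing.assert_array_equal(r1.Z_star, r2.Z_star)

    def test_huge_lambda_kills_P(self, small_fixture):
        res = fit_tglrr(small_fixture.X, TGLRRParams(lam=1e8, max_iter=150))
        np.testing.assert_array_equal(res.P_star, np.zeros_like(res.P_star))

    def test_max_iter_reached_is_not_an_error(self, small_fixture):
        res = fit_tglrr(small_fixture.X, TGLRRParams(max_iter=1))
        assert not res.converged
        assert res.n_iter == 1

    def test_fixed_penalty_still_feasible(self, small_fixture):
        """mu_max = mu0 with rho -> 1+ recovers fixed-penalty linearized
        ADMM, which still reaches (loose) feasibility on easy data."""
        p = TGLRRParams(mu0=50.0, mu_max=50.0, rho0=1.0 + 1e-9,
                        eps1=1e-3, max_iter=600)
        res = fit_tglrr(small_fixture.X, p)
        assert res.history[-1]["residual"] <= 1e-2

    def test_objective_decreases(self, small_fit):
        obj = small_fit.history_arrays()["objective"]
        assert obj[-1] < obj[0]

    def test_reduction_consistency_r0_beta0(self, small_fixture):
        """r=0, beta=0 solves the plain latent low-rank problem; runs with
        different seeds agree on the attained objective within 1%."""
        objs = []
        for seed in (0, 1):
            p = TGLRRParams(r=0, beta=0.0, seed=seed, max_iter=300)
            res = fit_tglrr(small_fixture.X, p)
            objs.append(res.history[-1]["objective"])
        assert abs(objs[0] - objs[1]) <= 0.01 * max(abs(objs[0]), 1e-12)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": -1.0},
            {"rho0": 1.0},
            {"mu0": 0.0},
            {"mu0": 2.0, "mu_max": 1.0},
            {"eps1": 0.0},
            {"max_iter": 0},
            {"r": -1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TGLRRParams(**kwargs)
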