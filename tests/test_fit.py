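"""Reduced-form OLS, recursive identification, residual bootstrap."""
import numpy as np
import pytest

from trendsvar import (
    Panel,
    ValidationError,
    beta_matrix_from_triple,
    bootstrap_fit,
    fit_reduced,
    identify_structural,
    simulate_svar,
)
from trendsvar.fit import ReducedFit, _unit_ldl

from ._oracles import ols_normal_equations, random_stable_params


def _noiseless_panel(c, d, b, t=60):
    k = len(c)
    x = np.zeros((t, k))
    x[0] = np.linalg.solve(np.eye(k) - b, c)
    for s in range(1, t):
        x[s] = c + d * (s + 1) + b @ x[s - 1]
    return Panel(x, "2004-01", tuple(f"V{i+1}" for i in range(k)))


def _reduced_from_sigma(sigma, k=3):
    labels = tuple(f"V{i+1}" for i in range(k))
    return ReducedFit(
        c=np.zeros(k), d=np.zeros(k), lag_matrix=np.zeros((k, k)),
        residuals=np.zeros((30, k)), sigma_u=np.asarray(sigma, dtype=float),
        t_eff=30, labels=labels,
    )


class TestFitReduced:
    def test_noiseless_panel_recovered_exactly(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0, 0.2, (3, 3))
        c = np.array([0.5, -1.0, 2.0])
        d = np.array([0.01, -0.005, 0.02])
        fit = fit_reduced(_noiseless_panel(c, d, b))
        assert np.allclose(fit.c, c, atol=1e-8)
        assert np.allclose(fit.d, d, atol=1e-8)
        assert np.allclose(fit.lag_matrix, b, atol=1e-8)

    def test_matches_normal_equation_oracle(self, ref_panel):
        fit = fit_reduced(ref_panel)
        c, d, b = ols_normal_equations(ref_panel)
        assert np.allclose(fit.c, c, atol=1e-8)
        assert np.allclose(fit.d, d, atol=1e-8)
        assert np.allclose(fit.lag_matrix, b, atol=1e-8)

    def test_matches_statsmodels_var(self, ref_panel):
        from statsmodels.tsa.api import VAR

        res = VAR(ref_panel.values).fit(maxlags=1, trend="ct")
        fit = fit_reduced(ref_panel)
        assert np.allclose(fit.lag_matrix, res.coefs[0], atol=1e-8)
        assert np.allclose(fit.c, res.params[0], atol=1e-8)
        assert np.allclose(fit.d, res.params[1], atol=1e-8)

    def test_residuals_orthogonal_to_regressors(self, ref_panel):
        fit = fit_reduced(ref_panel)
        x = ref_panel.values
        z = np.column_stack(
            [np.ones(fit.t_eff), np.arange(2, ref_panel.n_obs + 1), x[:-1]]
        )
        assert np.max(np.abs(z.T @ fit.residuals)) < 1e-8

    def test_too_small_panel_rejected(self):
        panel = Panel(np.random.default_rng(0).normal(size=(4, 3)), "2004-01", ("A", "B", "C"))
        with pytest.raises(ValidationError):
            fit_reduced(panel)

    def test_rank_deficient_regressors_rejected(self):
        t = 40
        x = np.column_stack(
            [np.full(t, 2.0), np.random.default_rng(3).normal(size=(t, 2))]
        )
        with pytest.raises(ValidationError):
            fit_reduced(Panel(x, "2004-01", ("A", "B", "C")))


class TestIdentify:
    def test_orthogonal_shocks_give_zero_betas(self):
        fit = identify_structural(_reduced_from_sigma(np.eye(3)))
        assert np.allclose(fit.params.beta, 0)
        assert np.allclose(fit.params.shock_scales, 1)

    def test_ldl_round_trip_recovers_known_structure(self):
        beta = beta_matrix_from_triple(0.47, 0.07, 0.36)
        lam = np.diag([1.0, 1.006, 0.957])
        impact = np.linalg.inv(np.eye(3) - beta)
        sigma = impact @ lam @ impact.T
        fit = identify_structural(_reduced_from_sigma(sigma))
        assert fit.params.beta21 == pytest.approx(0.47, abs=1e-10)
        assert fit.params.beta31 == pytest.approx(0.07, abs=1e-10)
        assert fit.params.beta32 == pytest.approx(0.36, abs=1e-10)
        assert np.allclose(fit.params.shock_scales**2, np.diag(lam), atol=1e-10)

    def test_zero_diagonal_sigma_rejected(self):
        sigma = np.eye(3)
        sigma[1, 1] = 0.0
        with pytest.raises(ValidationError, match="minor"):
            identify_structural(_reduced_from_sigma(sigma))

    def test_identification_identity_on_random_fits(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            params = random_stable_params(rng)
            panel = simulate_svar(params, n_months=200, seed=int(rng.integers(2**31)))
            fit = identify_structural(fit_reduced(panel))
            a0 = fit.params.a0
            prod = a0 @ fit.reduced.sigma_u @ a0.T
            off = prod - np.diag(np.diag(prod))
            assert np.max(np.abs(off)) <= 1e-10 * np.max(np.diag(prod))

    def test_reordering_changes_betas_not_reduced_form(self, ref_panel):
        reduced = fit_reduced(ref_panel)
        sigma_before = reduced.sigma_u.copy()
        b_before = reduced.lag_matrix.copy()
        default = identify_structural(reduced)
        flipped = identify_structural(reduced, ordering=("GP", "GC", "VA"))
        assert np.array_equal(reduced.sigma_u, sigma_before)
        assert np.array_equal(reduced.lag_matrix, b_before)
        assert flipped.params.beta21 != pytest.approx(default.params.beta21)
        # the reduced form is shared; only the structural reading moved
        perm = [2, 1, 0]
        assert np.allclose(flipped.params.lag_matrix, b_before[np.ix_(perm, perm)])


class TestBootstrap:
    def test_same_seed_identical_ses(self, ref_panel):
        a = bootstrap_fit(ref_panel, n_boot=150, seed=5)
        b = bootstrap_fit(ref_panel, n_boot=150, seed=5)
        assert np.array_equal(a.standard_errors.beta, b.standard_errors.beta)
        assert np.array_equal(a.standard_errors.lag_matrix, b.standard_errors.lag_matrix)

    def test_small_n_boot_rejected(self, ref_panel):
        with pytest.raises(ValidationError):
            bootstrap_fit(ref_panel, n_boot=10)

    def test_root_t_shrinkage_of_ses(self, ref_params):
        small = simulate_svar(ref_params, n_months=168, seed=31)
        big = simulate_svar(ref_params, n_months=16 * 168, seed=32)
        se_small = bootstrap_fit(small, n_boot=300, seed=1).standard_errors.beta[1, 0]
        se_big = bootstrap_fit(big, n_boot=300, seed=2).standard_errors.beta[1, 0]
        ratio = se_small / se_big
        assert 2.5 <= ratio <= 6.0
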