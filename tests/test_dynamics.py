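"""Impulse responses, variance decomposition, scale back-out, bands."""
import numpy as np
import pytest

from trendsvar import (
    ValidationError,
    back_out_shock_scales,
    beta_matrix_from_triple,
    bootstrap_irf_bands,
    compute_fevd,
    compute_irf,
    fit_reduced,
    identify_structural,
    impulse_matrix,
    simulate_svar,
    worked_example,
)
from trendsvar.types import StructuralParams

from ._oracles import mc_irf_path_difference, random_stable_params


def _params(beta_triple=(0.0, 0.0, 0.0), b=None, scales=(1.0, 1.0, 1.0)):
    return StructuralParams(
        alpha=np.zeros(3),
        mu=np.zeros(3),
        beta=beta_matrix_from_triple(*beta_triple),
        lag_matrix=np.zeros((3, 3)) if b is None else np.asarray(b),
        shock_scales=np.asarray(scales),
    )


class TestImpulseMatrix:
    def test_identity_when_no_contemporaneous_links(self):
        assert np.allclose(impulse_matrix(_params()), np.eye(3))

    def test_third_row_by_forward_substitution(self):
        theta0 = impulse_matrix(_params((0.47, 0.07, 0.36)))
        assert np.allclose(theta0[2], [0.07 + 0.36 * 0.47, 0.36, 1.0])

    def test_upper_triangle_always_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            theta0 = impulse_matrix(random_stable_params(rng))
            assert np.allclose(np.triu(theta0, 1), 0.0)


class TestIrf:
    def test_no_propagation_without_lags(self):
        dyn = compute_irf(_params((0.3, 0.1, 0.2)), horizon=6)
        assert np.allclose(dyn.theta[1:], 0.0)

    def test_matches_monte_carlo_path_difference(self, ref_params):
        horizon = 8
        dyn = compute_irf(ref_params, horizon=horizon)
        est, se = mc_irf_path_difference(ref_params, impulse=0, horizon=horizon, n_rep=60_000, seed=77)
        assert np.all(np.abs(est - dyn.theta[:, :, 0]) < 3 * se)

    def test_shocks_decay_under_reference_dynamics(self, ref_params):
        dyn = compute_irf(ref_params, horizon=12)
        assert np.linalg.norm(dyn.theta[12]) < np.linalg.norm(dyn.theta[1])

    def test_negative_horizon_rejected(self, ref_params):
        with pytest.raises(ValidationError):
            compute_irf(ref_params, horizon=-1)

    def test_unstable_lag_matrix_warns(self):
        p = _params(b=1.05 * np.eye(3))
        with pytest.warns(UserWarning):
            compute_irf(p, horizon=2)


class TestFevd:
    def test_first_variable_period1_row_is_pure_own_shock(self, ref_panel):
        fit = identify_structural(fit_reduced(ref_panel))
        dyn = compute_fevd(fit, horizons=(1,))
        assert np.allclose(dyn.fevd[0, 0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_rows_sum_to_one_everywhere(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            dyn = compute_fevd(random_stable_params(rng), horizons=(1, 3, 9))
            assert np.allclose(dyn.fevd.sum(axis=2), 1.0, atol=1e-10)

    def test_printed_period2_row_reproduced(self, ref_params):
        dyn = compute_fevd(ref_params, horizons=(2,))
        assert np.allclose(dyn.fevd[0, 1], [0.18, 0.81, 0.01], atol=0.01)

    def test_horizon_zero_rejected(self, ref_params):
        with pytest.raises(ValidationError):
            compute_fevd(ref_params, horizons=(0,))

    def test_shares_converge_for_stable_dynamics(self, ref_params):
        a = compute_fevd(ref_params, horizons=(60,)).fevd[0]
        b = compute_fevd(ref_params, horizons=(120,)).fevd[0]
        assert np.max(np.abs(a - b)) < 1e-6


class TestBackOutScales:
    def test_identity_shares_give_unit_scales(self):
        sigma = back_out_shock_scales(np.zeros((3, 3)), np.eye(3))
        assert np.allclose(sigma, 1.0)

    def test_second_scale_closed_form(self):
        beta = beta_matrix_from_triple(0.47, 0.07, 0.36)
        shares = np.array([[1, 0, 0], [0.18, 0.82, 0.0], [0.05, 0.11, 0.84]])
        sigma = back_out_shock_scales(beta, shares)
        assert sigma[1] == pytest.approx(0.47 * np.sqrt(0.82 / 0.18), abs=1e-12)

    def test_round_trip_from_exact_shares(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            params = random_stable_params(rng)
            truth = params.shock_scales / params.shock_scales[0]
            shares = compute_fevd(params, horizons=(1,)).fevd[0]
            sigma = back_out_shock_scales(params.beta, shares)
            # rows without contemporaneous links are unidentified from shares
            theta0 = impulse_matrix(params)
            for i in range(3):
                if np.any(theta0[i, :i] != 0):
                    assert sigma[i] == pytest.approx(truth[i], abs=1e-10)

    def test_degenerate_zero_share_rejected(self):
        beta = beta_matrix_from_triple(0.5, 0.0, 0.0)
        shares = np.array([[1, 0, 0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValidationError):
            back_out_shock_scales(beta, shares)


class TestIrfBands:
    def test_same_seed_identical_bands(self, ref_panel):
        fit = identify_structural(fit_reduced(ref_panel))
        a = bootstrap_irf_bands(ref_panel, fit, n_boot=150, horizon=6, seed=9)
        b = bootstrap_irf_bands(ref_panel, fit, n_boot=150, horizon=6, seed=9)
        assert np.array_equal(a.ci_lower, b.ci_lower)
        assert np.array_equal(a.ci_upper, b.ci_upper)

    def test_point_irf_inside_own_band(self, ref_panel):
        fit = identify_structural(fit_reduced(ref_panel))
        dyn = bootstrap_irf_bands(ref_panel, fit, n_boot=400, horizon=6, seed=10)
        assert np.all(dyn.theta <= dyn.ci_upper + 1e-12)
        assert np.all(dyn.theta >= dyn.ci_lower - 1e-12)

    def test_null_effect_band_covers_zero(self, ref_params):
        # truth in which VA shocks never reach GP (no contemporaneous link
        # and no lagged channel out of VA), so the true VA->GP response is
        # zero at every horizon and the 95% band should cover zero
        b = ref_params.lag_matrix.copy()
        b[1, 0] = b[2, 0] = 0.0
        params = StructuralParams(
            ref_params.alpha, ref_params.mu,
            beta_matrix_from_triple(0.0, 0.0, ref_params.beta32),
            b, ref_params.shock_scales,
        )
        hits = 0
        n_sets = 15
        for seed in range(n_sets):
            panel = simulate_svar(params, n_months=168, seed=500 + seed)
            fit = identify_structural(fit_reduced(panel))
            dyn = bootstrap_irf_bands(panel, fit, n_boot=200, horizon=6, seed=seed)
            if np.all((dyn.ci_lower[:, 2, 0] <= 0.0) & (0.0 <= dyn.ci_upper[:, 2, 0])):
                hits += 1
        assert hits >= 12

    def test_bands_narrow_with_sample_size(self, ref_params):
        widths = {}
        for label, t, base in (("small", 120, 900), ("large", 2000, 950)):
            acc = 0.0
            for seed in range(8):
                panel = simulate_svar(ref_params, n_months=t, seed=base + seed)
                fit = identify_structural(fit_reduced(panel))
                dyn = bootstrap_irf_bands(panel, fit, n_boot=200, horizon=4, seed=seed)
                acc += float(np.mean(dyn.ci_upper - dyn.ci_lower))
            widths[label] = acc / 8
        assert widths["large"] < widths["small"]
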