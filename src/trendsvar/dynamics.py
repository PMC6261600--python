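"""Impulse responses, forecast-error variance decomposition, bootstrap bands.

For the structural VAR(1) with reduced-form lag matrix ``B`` and impact
matrix ``Theta0 = L diag(sigma)`` (``L = A0^{-1}``), the response of the
system ``h`` months after a one-standard-deviation structural shock is

    Theta_h = B^h Theta0,

and the share of the ``H``-month-ahead forecast-error variance of variable
``i`` attributable to shock ``j`` is

    fevd(i, j, H) = sum_{h=0}^{H-1} Theta_h[i,j]^2 / sum_j sum_h Theta_h[i,j]^2.

Period 1 therefore equals the contemporaneous decomposition, so the
first-ordered variable's period-1 row is always (1, 0, ..., 0) under a
recursive ordering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .fit import StructuralFit, _bootstrap_draws, fit_reduced
from .types import Panel, StructuralParams, spectral_radius

FitLike = Union[StructuralFit, StructuralParams]

DEFAULT_FEVD_HORIZONS = (1, 2, 3, 6, 12)
DEFAULT_IRF_HORIZON = 12


@dataclass
class ShockDynamics:
    """Container for IRF matrices, FEVD shares and bootstrap bands.

    ``theta[h, i, j]`` is the month-``h`` response of variable ``i`` to a
    one-SD shock in variable ``j`` (log-interest units).  ``fevd[m, i, j]``
    is the variance share of shock ``j`` in variable ``i`` at horizon
    ``fevd_horizons[m]``; rows sum to one.
    """

    labels: tuple[str, ...]
    theta: Optional[np.ndarray] = None  # (H+1, K, K)
    horizon: Optional[int] = None
    fevd: Optional[np.ndarray] = None  # (n_horizons, K, K)
    fevd_horizons: Optional[tuple[int, ...]] = None
    ci_lower: Optional[np.ndarray] = None  # like theta
    ci_upper: Optional[np.ndarray] = None


def _params_of(fit: FitLike) -> StructuralParams:
    return fit.params if isinstance(fit, StructuralFit) else fit


def impulse_matrix(fit: FitLike) -> np.ndarray:
    """Contemporaneous response to one-SD structural shocks, Theta0 = L diag(sigma)."""
    p = _params_of(fit)
    return p.impact @ np.diag(p.shock_scales)


def _theta_path(params: StructuralParams, horizon: int, unit_shocks: bool = False) -> np.ndarray:
    theta0 = params.impact if unit_shocks else impulse_matrix(params)
    out = np.empty((horizon + 1, params.n_vars, params.n_vars))
    out[0] = theta0
    for h in range(1, horizon + 1):
        out[h] = params.lag_matrix @ out[h - 1]
    return out


def compute_irf(
    fit: FitLike, horizon: int = DEFAULT_IRF_HORIZON, unit_shocks: bool = False
) -> ShockDynamics:
    """Impulse responses Theta_h = B^h Theta0 for h = 0..horizon.

    Shocks are one structural standard deviation by default; pass
    ``unit_shocks=True`` for unit-impulse responses.  An unstable lag
    matrix triggers a warning, not an error.
    """
    if horizon < 0:
        raise ValidationError("horizon must be >= 0")
    params = _params_of(fit)
    if spectral_radius(params.lag_matrix) >= 1.0:
        warnings.warn("lag matrix spectral radius >= 1; responses will not decay")
    return ShockDynamics(
        labels=params.labels,
        theta=_theta_path(params, horizon, unit_shocks),
        horizon=horizon,
    )


def compute_fevd(
    fit: FitLike, horizons: Sequence[int] = DEFAULT_FEVD_HORIZONS
) -> ShockDynamics:
    """Forecast-error variance decomposition at the given horizons (months)."""
    horizons = tuple(int(h) for h in horizons)
    if any(h < 1 for h in horizons):
        raise ValidationError("FEVD horizons must be >= 1")
    params = _params_of(fit)
    h_max = max(horizons)
    theta = _theta_path(params, h_max - 1)
    cum = np.cumsum(theta**2, axis=0)  # cum[h] sums Theta_0..Theta_h
    shares = np.empty((len(horizons), params.n_vars, params.n_vars))
    for m, h in enumerate(horizons):
        mse = cum[h - 1]
        shares[m] = mse / mse.sum(axis=1, keepdims=True)
    return ShockDynamics(
        labels=params.labels,
        theta=theta,
        horizon=h_max - 1,
        fevd=shares,
        fevd_horizons=horizons,
    )


def back_out_shock_scales(beta: np.ndarray, period1_shares: np.ndarray) -> np.ndarray:
    """Recover structural shock SDs from the period-1 FEVD rows.

    The period-1 decomposition of row ``i`` depends only on the
    contemporaneous impact ``Theta0[i, :] = (L[i,1] s1, ..., s_i, 0, ...)``,
    so with ``s1`` normalised to one each subsequent scale follows from its
    own-share ratio:

        s_i^2 = share(i,i) / (1 - share(i,i)) * sum_{j<i} Theta0[i,j]^2,

    which pools every cross share in the row (for a single predecessor it
    reduces to ``s2 = beta21 * s1 * sqrt(share22/share21)``).  Rows whose
    own share is one and whose contemporaneous coefficients are all zero
    are unidentified from shares alone; their scale defaults to one.
    """
    beta = np.asarray(beta, dtype=float)
    shares = np.asarray(period1_shares, dtype=float)
    k = beta.shape[0]
    if shares.shape != (k, k):
        raise ValidationError("period1_shares must be K x K")
    if np.any(np.abs(shares.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("period-1 FEVD rows must sum to 1")
    impact = np.linalg.inv(np.eye(k) - beta)
    sigma = np.ones(k)
    for i in range(1, k):
        cross = impact[i, :i] * sigma[:i]
        own = shares[i, i]
        if np.allclose(cross, 0.0):
            continue  # row is its own shock; scale unidentified, stays 1
        if 1.0 - own <= 0:
            raise ValidationError(
                f"row {i + 1}: own share is 1 but contemporaneous coefficients are nonzero"
            )
        sigma[i] = np.sqrt(own / (1.0 - own) * np.sum(cross**2))
    return sigma


def bootstrap_irf_bands(
    panel: Panel,
    fit: StructuralFit,
    n_boot: int = 1000,
    horizon: int = DEFAULT_IRF_HORIZON,
    seed: Optional[int] = None,
) -> ShockDynamics:
    """Percentile 95% bootstrap bands around the impulse responses.

    Reuses the recursive residual bootstrap: each replicate panel is
    refitted, re-identified, and propagated to its own IRF; bands are the
    pointwise 2.5/97.5 percentiles of the replicate IRFs, reported as-is
    (no recentering or clipping around the point estimate).
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100 for stable quantiles")
    if horizon < 0:
        raise ValidationError("horizon must be >= 0")
    point = compute_irf(fit, horizon)
    reduced = fit.reduced if fit.reduced is not None else fit_reduced(panel)
    rng = np.random.default_rng(seed)
    draws = _bootstrap_draws(panel, reduced, n_boot, rng)

    theta_b = np.empty((n_boot, horizon + 1, point.theta.shape[1], point.theta.shape[2]))
    theta_b[:, 0] = draws["impact"] * draws["shock_scales"][:, None, :]
    b = draws["lag_matrix"]
    for h in range(1, horizon + 1):
        theta_b[:, h] = b @ theta_b[:, h - 1]

    lower, upper = np.percentile(theta_b, [2.5, 97.5], axis=0)
    return ShockDynamics(
        labels=point.labels,
        theta=point.theta,
        horizon=horizon,
        ci_lower=lower,
        ci_upper=upper,
    )
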