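"""Pre-fit diagnostics: per-series stationarity and lag-order selection.

Stationarity uses the augmented Dickey-Fuller test with constant and
trend, consistent with the model's deterministic terms (p-values from the
MacKinnon response surface via statsmodels).  Lag order is chosen by the
multivariate AIC

    AIC(p) = ln det(Sigma_hat_u(p)) + 2 * m(p) / T_eff,

with ``m(p) = K (2 + K p)`` mean-equation parameters, all orders compared
on the common effective sample and ties broken toward the smaller lag.
Only the argmin is meaningful across datasets; the AIC level depends on
the data scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .errors import ValidationError
from .types import Panel, spectral_radius

_REGRESSIONS = {"constant": "c", "constant+trend": "ct"}


@dataclass
class DiagnosticsReport:
    """ADF results per column plus the AIC lag choice."""

    adf: dict  # label -> (statistic, p_value)
    aic_by_lag: dict  # lag -> AIC
    chosen_lag: int
    stable: bool  # spectral radius of the fitted companion matrix < 1


def adf_test(
    series: np.ndarray,
    regression: str = "constant+trend",
    max_lag: Optional[int] = None,
) -> tuple[float, float]:
    """Augmented Dickey-Fuller unit-root test; returns (statistic, p-value)."""
    series = np.asarray(series, dtype=float).ravel()
    if regression not in _REGRESSIONS:
        raise ValidationError(f"regression must be one of {sorted(_REGRESSIONS)}")
    if len(series) <= 10 + (max_lag or 0):
        raise ValidationError(
            f"series too short for ADF: T={len(series)}, need > {10 + (max_lag or 0)}"
        )
    if np.ptp(series) == 0:
        raise ValidationError("constant series: ADF regression is degenerate")
    stat, pvalue, *_ = adfuller(series, maxlag=max_lag, regression=_REGRESSIONS[regression])
    return float(stat), float(pvalue)


def choose_lag(aic_by_lag: dict) -> int:
    """Argmin over lags; ties go to the smallest lag."""
    best = min(aic_by_lag.values())
    return min(p for p, a in aic_by_lag.items() if a == best)


def _var_aic(panel: Panel, p: int, p_max: int) -> float:
    """AIC of a VAR(p) with constant and trend on the common sample."""
    x = panel.values
    t, k = x.shape
    t_idx = np.arange(p_max + 1, t + 1, dtype=float)
    y = x[p_max:]
    lags = [x[p_max - j : t - j] for j in range(1, p + 1)]
    z = np.column_stack([np.ones(len(t_idx)), t_idx] + lags)
    coef, *_ = np.linalg.lstsq(z, y, rcond=None)
    resid = y - z @ coef
    t_eff = len(y)
    sigma = resid.T @ resid / t_eff
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValidationError("degenerate residual covariance in lag selection")
    m = k * (2 + k * p)
    return float(logdet + 2.0 * m / t_eff)


def select_lag(panel: Panel, p_max: int = 4, include_adf: bool = True) -> DiagnosticsReport:
    """Fit VAR(p) for p = 1..p_max and pick the AIC-minimising order."""
    if p_max < 1:
        raise ValidationError("p_max must be >= 1")
    k = panel.n_vars
    if panel.n_obs - p_max < 3 * k + 2:
        raise ValidationError(
            f"insufficient data for lag selection: T={panel.n_obs}, p_max={p_max}"
        )
    aic = {p: _var_aic(panel, p, p_max) for p in range(1, p_max + 1)}
    chosen = choose_lag(aic)

    # stability of the chosen order via the companion matrix
    x = panel.values
    t = panel.n_obs
    t_idx = np.arange(chosen + 1, t + 1, dtype=float)
    y = x[chosen:]
    lags = [x[chosen - j : t - j] for j in range(1, chosen + 1)]
    z = np.column_stack([np.ones(len(t_idx)), t_idx] + lags)
    coef, *_ = np.linalg.lstsq(z, y, rcond=None)
    bmats = [coef[2 + j * k : 2 + (j + 1) * k].T for j in range(chosen)]
    companion = np.zeros((k * chosen, k * chosen))
    companion[:k] = np.hstack(bmats)
    if chosen > 1:
        companion[k:, : k * (chosen - 1)] = np.eye(k * (chosen - 1))
    stable = spectral_radius(companion) < 1.0

    report = DiagnosticsReport(adf={}, aic_by_lag=aic, chosen_lag=chosen, stable=stable)
    if include_adf:
        for j, label in enumerate(panel.columns):
            report.adf[label] = adf_test(panel.values[:, j])
    return report
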