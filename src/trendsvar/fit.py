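"""Reduced-form estimation, recursive identification, residual bootstrap.

Estimation is equation-by-equation OLS of ``x_t`` on ``(1, t, x_{t-1})``;
with identical regressors in every equation this coincides with
multivariate least squares.  The structural contemporaneous matrix is then
identified from the unit-diagonal LDL' factorisation of the residual
covariance ``Sigma_u = L Lambda L'``: under a recursive (Wold) ordering the
model is just-identified and ``A0 = L^{-1}``, with the structural shock
variances on the diagonal of ``Lambda``.

Uncertainty comes from a recursive residual bootstrap: centred residual
rows are resampled with replacement, panels are rebuilt from the fitted
dynamics conditioning on the first observed row, and each replicate is
refitted and re-identified.  The replicate draws are retained so the same
machinery serves coefficient standard errors and impulse-response bands.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .types import Panel, StructuralParams, spectral_radius


@dataclass
class ReducedFit:
    """Least-squares estimates of the reduced form x_t = c + d t + B x_{t-1} + u_t."""

    c: np.ndarray
    d: np.ndarray
    lag_matrix: np.ndarray  # reduced-form B
    residuals: np.ndarray  # T_eff x K
    sigma_u: np.ndarray  # residual covariance, denominator T_eff
    t_eff: int
    labels: tuple[str, ...]

    @property
    def n_vars(self) -> int:
        return len(self.c)

    @property
    def stable(self) -> bool:
        return spectral_radius(self.lag_matrix) < 1.0


@dataclass
class ParamArrays:
    """Parameter-shaped arrays without validation (bootstrap SDs etc.)."""

    alpha: np.ndarray
    mu: np.ndarray
    beta: np.ndarray
    lag_matrix: np.ndarray
    shock_scales: np.ndarray


@dataclass
class StructuralFit:
    """Identified structural parameters, optionally with bootstrap SEs.

    ``draws`` holds the raw bootstrap replicate parameters (stacked along
    axis 0) when the fit came from :func:`bootstrap_fit`; downstream code
    uses them for percentile bands.
    """

    params: StructuralParams
    ordering: tuple[str, ...]
    reduced: ReducedFit
    standard_errors: Optional[ParamArrays] = None
    draws: Optional[dict] = None

    @property
    def n_vars(self) -> int:
        return self.params.n_vars


def _design(panel: Panel) -> tuple[np.ndarray, np.ndarray]:
    """Response rows 2..T and regressor matrix [1, t, x_{t-1}]."""
    x = panel.values
    t_idx = np.arange(2, panel.n_obs + 1, dtype=float)
    z = np.column_stack([np.ones(len(t_idx)), t_idx, x[:-1]])
    return x[1:], z


def fit_reduced(panel: Panel) -> ReducedFit:
    """Equation-by-equation OLS of the VAR(1) with constant and linear trend.

    The trend index runs 1..T over the panel, so the effective sample
    (rows 2..T) carries trend values 2..T.  The residual covariance uses
    denominator ``T_eff`` (not ``T_eff - k``).
    """
    k = panel.n_vars
    if panel.n_obs < k + 3:
        raise ValidationError(
            f"panel too short to estimate: T={panel.n_obs}, need at least {k + 3}"
        )
    y, z = _design(panel)
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValidationError("rank-deficient regressor matrix (collinear columns)")
    coef, *_ = np.linalg.lstsq(z, y, rcond=None)
    resid = y - z @ coef
    t_eff = y.shape[0]
    return ReducedFit(
        c=coef[0].copy(),
        d=coef[1].copy(),
        lag_matrix=coef[2:].T.copy(),
        residuals=resid,
        sigma_u=resid.T @ resid / t_eff,
        t_eff=t_eff,
        labels=panel.columns,
    )


def _unit_ldl(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Factor sigma = L diag(lam) L' with L unit lower triangular."""
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        minors = [np.linalg.det(sigma[: i + 1, : i + 1]) for i in range(sigma.shape[0])]
        bad = next(i for i, m in enumerate(minors) if m <= 0)
        raise ValidationError(
            f"residual covariance not positive definite: leading minor {bad + 1} "
            f"is {minors[bad]:.3e}"
        ) from None
    diag = np.diag(chol)
    return chol / diag, diag**2


def identify_structural(
    reduced: ReducedFit, ordering: Optional[Sequence[str]] = None
) -> StructuralFit:
    """Recursive identification of the contemporaneous structure.

    ``ordering`` permutes the Wold causal order before factorising; the
    reduced form itself is order-invariant, only the structural
    interpretation changes.  Returns point estimates only.
    """
    labels = reduced.labels
    if ordering is None:
        ordering = labels
    ordering = tuple(ordering)
    if sorted(ordering) != sorted(labels):
        raise ValidationError(f"ordering must be a permutation of {labels}")
    perm = [labels.index(name) for name in ordering]
    p = np.asarray(perm)

    sigma = reduced.sigma_u[np.ix_(p, p)]
    impact, lam = _unit_ldl(sigma)
    a0 = np.linalg.inv(impact)
    beta = np.eye(len(p)) - a0
    params = StructuralParams(
        alpha=a0 @ reduced.c[p],
        mu=a0 @ reduced.d[p],
        beta=beta,
        lag_matrix=reduced.lag_matrix[np.ix_(p, p)],
        shock_scales=np.sqrt(lam),
        labels=ordering,
    )
    return StructuralFit(params=params, ordering=ordering, reduced=reduced)


# ---------------------------------------------------------------------------
# residual bootstrap (vectorised across replicates)
# ---------------------------------------------------------------------------


def _bootstrap_draws(
    panel: Panel, reduced: ReducedFit, n_boot: int, rng: np.random.Generator
) -> dict:
    """Refit + re-identify on ``n_boot`` resampled panels; return stacked draws."""
    resid = reduced.residuals - reduced.residuals.mean(axis=0)
    t_eff, k = resid.shape
    idx = rng.integers(0, t_eff, size=(n_boot, t_eff))
    u = resid[idx]  # (n_boot, t_eff, k)

    # rebuild panels recursively, conditioning on the first observed row
    x = np.empty((n_boot, t_eff + 1, k))
    x[:, 0] = panel.values[0]
    c, d, b = reduced.c, reduced.d, reduced.lag_matrix
    for s in range(t_eff):
        x[:, s + 1] = c + d * (s + 2) + x[:, s] @ b.T + u[:, s]

    # batched OLS via normal equations on the shared design shape
    t_idx = np.arange(2, t_eff + 2, dtype=float)
    z = np.empty((n_boot, t_eff, k + 2))
    z[:, :, 0] = 1.0
    z[:, :, 1] = t_idx
    z[:, :, 2:] = x[:, :-1]
    y = x[:, 1:]
    gram = z.transpose(0, 2, 1) @ z
    coef = np.linalg.solve(gram, z.transpose(0, 2, 1) @ y)  # (n_boot, k+2, k)
    res = y - z @ coef
    sigma = res.transpose(0, 2, 1) @ res / t_eff

    chol = np.linalg.cholesky(sigma)
    diag = np.diagonal(chol, axis1=1, axis2=2)
    impact = chol / diag[:, None, :]
    a0 = np.linalg.inv(impact)
    eye = np.eye(k)
    return {
        "alpha": (a0 @ coef[:, 0, :, None])[:, :, 0],
        "mu": (a0 @ coef[:, 1, :, None])[:, :, 0],
        "beta": eye - a0,
        "lag_matrix": coef[:, 2:].transpose(0, 2, 1),
        "shock_scales": diag.copy(),
        "impact": impact,
    }


def bootstrap_fit(
    panel: Panel,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    ordering: Optional[Sequence[str]] = None,
) -> StructuralFit:
    """Point fit plus recursive-residual-bootstrap standard errors.

    Standard errors are bootstrap standard deviations; the replicate draws
    themselves are kept on the returned fit for percentile intervals.
    Fully reproducible given ``seed``.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100 for stable quantiles")
    if ordering is not None and tuple(ordering) != panel.columns:
        perm = [panel.columns.index(name) for name in ordering]
        panel = Panel(panel.values[:, perm], panel.start_month, tuple(ordering))
    reduced = fit_reduced(panel)
    fit = identify_structural(reduced)
    rng = np.random.default_rng(seed)
    draws = _bootstrap_draws(panel, reduced, n_boot, rng)
    fit.draws = draws
    fit.standard_errors = ParamArrays(
        alpha=draws["alpha"].std(axis=0, ddof=1),
        mu=draws["mu"].std(axis=0, ddof=1),
        beta=draws["beta"].std(axis=0, ddof=1),
        lag_matrix=draws["lag_matrix"].std(axis=0, ddof=1),
        shock_scales=draws["shock_scales"].std(axis=0, ddof=1),
    )
    return fit
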