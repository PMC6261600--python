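"""Independent oracles used by the tests.

These deliberately avoid the library's own code paths: OLS via explicit
pseudo-inverse normal equations, impulse responses via Monte-Carlo path
differences from a hand-rolled simulator, and stationary covariance via
the discrete Lyapunov equation.
"""
from __future__ import annotations

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from trendsvar.types import StructuralParams


def ols_normal_equations(panel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brute-force (c, d, B) via pinv of the normal equations."""
    x = panel.values
    t = x.shape[0]
    z = np.column_stack([np.ones(t - 1), np.arange(2, t + 1, dtype=float), x[:-1]])
    coef = np.linalg.pinv(z.T @ z) @ z.T @ x[1:]
    return coef[0], coef[1], coef[2:].T


def mc_irf_path_difference(
    params: StructuralParams, impulse: int, horizon: int, n_rep: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo IRF: mean difference between shocked and baseline paths.

    Baseline and shocked ensembles use independent shock draws; the
    shocked ensemble adds one structural SD to shock ``impulse`` at t=0.
    Deterministic terms are irrelevant to the difference and are dropped.
    Returns (estimate, standard_error), each (horizon+1, K).
    """
    rng = np.random.default_rng(seed)
    k = params.n_vars
    b = params.lag_matrix
    impact = params.impact
    scales = params.shock_scales

    def run(extra0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.zeros((n_rep, k))
        means = np.empty((horizon + 1, k))
        variances = np.empty((horizon + 1, k))
        for h in range(horizon + 1):
            e = rng.standard_normal((n_rep, k)) * scales
            if h == 0:
                e = e + extra0
            x = x @ b.T + e @ impact.T
            means[h] = x.mean(axis=0)
            variances[h] = x.var(axis=0, ddof=1)
        return means, variances

    impulse_vec = np.zeros(k)
    impulse_vec[impulse] = scales[impulse]
    m0, v0 = run(np.zeros(k))
    m1, v1 = run(impulse_vec)
    return m1 - m0, np.sqrt((v0 + v1) / n_rep)


def stationary_covariance(params: StructuralParams) -> np.ndarray:
    """Solve Sigma = B Sigma B' + L Lambda L'."""
    impact = params.impact
    q = impact @ np.diag(params.shock_scales**2) @ impact.T
    return solve_discrete_lyapunov(params.lag_matrix, q)


def random_stable_params(rng: np.random.Generator, k: int = 3) -> StructuralParams:
    """Random stationary parameter set with a strict recursive structure."""
    beta = np.tril(rng.uniform(-0.6, 0.6, size=(k, k)), -1)
    b = rng.normal(0.0, 0.25, size=(k, k))
    rho = np.max(np.abs(np.linalg.eigvals(b)))
    if rho >= 0.9:
        b *= 0.7 / rho
    return StructuralParams(
        alpha=rng.normal(0.0, 1.0, size=k),
        mu=rng.normal(0.0, 0.002, size=k),
        beta=beta,
        lag_matrix=b,
        shock_scales=np.exp(rng.normal(0.0, 0.3, size=k)),
        labels=tuple(f"V{i + 1}" for i in range(k)),
    )
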