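"""Reference point estimates for the three-variable search-interest system.

These are the published point estimates of the U.S. 2004-2017 monthly
search-interest SVAR(1) in violent-attack (VA), gun-control (GC) and
gun-purchase (GP) interest.  They serve two purposes throughout the
package: a deterministic worked example (propagating the printed
coefficients reproduces the printed variance decompositions), and the
ground truth for the synthetic-data study conditions.

The structural shock standard deviations were not published; they are
recovered from the period-1 variance-decomposition rows by
:func:`trendsvar.dynamics.back_out_shock_scales`, with the first scale
normalised to one.
"""
from __future__ import annotations

import numpy as np

from .dynamics import back_out_shock_scales
from .types import StructuralParams, beta_matrix_from_triple

LABELS = ("VA", "GC", "GP")

#: Structural levels alpha, log-interest units.
ALPHA = (2.48, 1.37, 2.02)

#: Trend slopes mu, reported as mu * 10^3 per month.
TREND_PER_1000 = (3.11, 0.14, 2.37)

#: Contemporaneous coefficients (beta21, beta31, beta32).
BETA_TRIPLE = (0.47, 0.07, 0.36)

#: First-order lag coefficients, read as the reduced-form matrix B.
LAG_MATRIX = (
    (0.34, 0.39, -0.34),
    (-0.01, 0.56, 0.15),
    (-0.13, 0.22, 0.48),
)

#: Published forecast-error variance decomposition, rows in Wold order,
#: keyed by horizon in months.
FEVD_TABLE = {
    1: ((1.00, 0.00, 0.00), (0.18, 0.82, 0.00), (0.05, 0.11, 0.84)),
    2: ((0.86, 0.05, 0.08), (0.18, 0.81, 0.01), (0.04, 0.18, 0.78)),
    3: ((0.82, 0.07, 0.11), (0.18, 0.80, 0.02), (0.04, 0.22, 0.74)),
    6: ((0.80, 0.09, 0.11), (0.17, 0.79, 0.04), (0.04, 0.22, 0.74)),
    12: ((0.80, 0.09, 0.11), (0.17, 0.79, 0.04), (0.04, 0.22, 0.74)),
}

FEVD_HORIZONS = (1, 2, 3, 6, 12)


def shock_scales() -> np.ndarray:
    """Shock SDs implied by the period-1 FEVD rows (sigma_1 = 1)."""
    beta = beta_matrix_from_triple(*BETA_TRIPLE)
    return back_out_shock_scales(beta, np.asarray(FEVD_TABLE[1], dtype=float))


def params() -> StructuralParams:
    """Full reference parameter set, usable as simulation ground truth."""
    return StructuralParams(
        alpha=np.asarray(ALPHA),
        mu=np.asarray(TREND_PER_1000) / 1000.0,
        beta=beta_matrix_from_triple(*BETA_TRIPLE),
        lag_matrix=np.asarray(LAG_MATRIX),
        shock_scales=shock_scales(),
        labels=LABELS,
    )
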