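"""Table rendering and tidy CSV output for fits, FEVD, IRFs and grids.

Cells print as ``x.xx(se)`` with half-up rounding to two decimals; trend
slopes print as mu * 10^3 per month.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ShockDynamics
from .errors import ValidationError
from .fit import StructuralFit
from .grid import GridResult


def round_half_up(x: float, decimals: int = 2) -> str:
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _cell(est: float, se: float) -> str:
    return f"{round_half_up(est)}({round_half_up(se)})"


def render_table1(fit: StructuralFit, dyn: ShockDynamics) -> str:
    """Paper-style parameter + variance-decomposition table as text.

    One block per variable: level, trend (x10^3), the contemporaneous
    coefficient row (unit diagonal, zeros above), the lagged row of B,
    then the FEVD shares at each configured horizon.
    """
    if fit.standard_errors is None:
        raise ValidationError(
            "fit has no standard errors; run bootstrap_fit before rendering"
        )
    if dyn.fevd is None or dyn.fevd_horizons is None:
        raise ValidationError("dynamics object has no FEVD block")
    p, se = fit.params, fit.standard_errors
    labels = list(p.labels)
    k = p.n_vars
    contemporaneous = np.eye(k) + p.beta  # printed as coefficient rows

    lines = []
    header = (
        ["variable", "level", "trend(x10^3)"]
        + [f"beta_{l}" for l in labels]
        + [f"lag_{l}" for l in labels]
    )
    lines.append("  ".join(f"{h:>12}" for h in header))
    for i, lbl in enumerate(labels):
        cells = [
            _cell(p.alpha[i], se.alpha[i]),
            _cell(p.mu[i] * 1e3, se.mu[i] * 1e3),
        ]
        cells += [_cell(contemporaneous[i, j], se.beta[i, j]) for j in range(k)]
        cells += [_cell(p.lag_matrix[i, j], se.lag_matrix[i, j]) for j in range(k)]
        lines.append("  ".join([f"{lbl:>12}"] + [f"{c:>12}" for c in cells]))

    lines.append("")
    lines.append("Forecast error variance decomposition (shock shares by row)")
    lines.append("  ".join(f"{h:>10}" for h in ["variable", "period"] + labels))
    for i, lbl in enumerate(labels):
        for m, h in enumerate(dyn.fevd_horizons):
            shares = [round_half_up(dyn.fevd[m, i, j]) for j in range(k)]
            lines.append("  ".join([f"{lbl:>10}", f"{h:>10}"] + [f"{s:>10}" for s in shares]))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# tidy CSV writers and their readers (round-trip safe)
# ---------------------------------------------------------------------------


def fit_frame(fit: StructuralFit) -> pd.DataFrame:
    p = fit.params
    se = fit.standard_errors
    rows = []

    def add(param, variable, shock, est, sd):
        rows.append(
            {"param": param, "variable": variable, "shock": shock,
             "estimate": float(est), "se": float(sd) if sd is not None else np.nan}
        )

    labels = p.labels
    for i, lbl in enumerate(labels):
        add("alpha", lbl, "", p.alpha[i], se.alpha[i] if se else None)
        add("mu", lbl, "", p.mu[i], se.mu[i] if se else None)
        add("shock_scale", lbl, "", p.shock_scales[i], se.shock_scales[i] if se else None)
        for j, src in enumerate(labels):
            if j < i:
                add("beta", lbl, src, p.beta[i, j], se.beta[i, j] if se else None)
            add("lag", lbl, src, p.lag_matrix[i, j], se.lag_matrix[i, j] if se else None)
    return pd.DataFrame(rows)


def write_fit_csv(fit: StructuralFit, path) -> None:
    fit_frame(fit).to_csv(path, index=False)


def read_fit_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame["shock"] = frame["shock"].fillna("")
    return frame


def fevd_frame(dyn: ShockDynamics) -> pd.DataFrame:
    if dyn.fevd is None:
        raise ValidationError("no FEVD block to write")
    rows = []
    for m, h in enumerate(dyn.fevd_horizons):
        for i, var in enumerate(dyn.labels):
            for j, shock in enumerate(dyn.labels):
                rows.append(
                    {"variable": var, "shock": shock, "horizon": h,
                     "share": float(dyn.fevd[m, i, j])}
                )
    return pd.DataFrame(rows)


def write_fevd_csv(dyn: ShockDynamics, path) -> None:
    fevd_frame(dyn).to_csv(path, index=False)


def irf_frame(dyn: ShockDynamics) -> pd.DataFrame:
    if dyn.theta is None:
        raise ValidationError("no IRF block to write")
    rows = []
    has_ci = dyn.ci_lower is not None
    for h in range(dyn.theta.shape[0]):
        for j, impulse in enumerate(dyn.labels):
            for i, response in enumerate(dyn.labels):
                rec = {"h": h, "impulse": impulse, "response": response,
                       "value": float(dyn.theta[h, i, j])}
                rec["lo95"] = float(dyn.ci_lower[h, i, j]) if has_ci else np.nan
                rec["hi95"] = float(dyn.ci_upper[h, i, j]) if has_ci else np.nan
                rows.append(rec)
    return pd.DataFrame(rows)


def write_irf_csv(dyn: ShockDynamics, path) -> None:
    irf_frame(dyn).to_csv(path, index=False)


def write_grid_csv(grid: GridResult, path) -> None:
    grid.to_frame().to_csv(path, index=False)


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
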