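"""Search-term robustness grid: refit the SVAR for every term combination.

Each submodel replaces the composite constructs by a single search term
per construct (its log series directly, no composite construction), so a
5x5x5 design yields 125 submodels and 375 contemporaneous coefficients.
Unestimable combinations are recorded with a reason, never dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fit import fit_reduced, identify_structural
from .ingest import TermSeries
from .types import DEFAULT_LABELS, Panel


@dataclass
class GridRow:
    combo: tuple[str, ...]  # one term name per construct, causal order
    beta21: float = np.nan
    beta31: float = np.nan
    beta32: float = np.nan
    status: str = "ok"
    reason: str = ""


@dataclass
class GridResult:
    ordering: tuple[str, ...]
    rows: list[GridRow]

    @property
    def n_combos(self) -> int:
        return len(self.rows)

    @property
    def betas(self) -> np.ndarray:
        """(n_combos, 3) array of (beta21, beta31, beta32); NaN where failed."""
        return np.array([[r.beta21, r.beta31, r.beta32] for r in self.rows])

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {f"{lbl.lower()}_term": t for lbl, t in zip(self.ordering, r.combo)}
            rec.update(
                beta21=r.beta21, beta31=r.beta31, beta32=r.beta32,
                status=r.status, reason=r.reason,
            )
            recs.append(rec)
        return pd.DataFrame(recs)


def run_grid(
    term_sets: Mapping[str, Sequence[TermSeries]],
    ordering: Sequence[str] = DEFAULT_LABELS,
    log_offset: float = 1.0,
) -> GridResult:
    """Fit one submodel per term combination; deterministic given input."""
    ordering = tuple(ordering)
    if sorted(term_sets.keys()) != sorted(ordering):
        raise ValidationError(f"term_sets keys must be {ordering}")
    sets = [list(term_sets[label]) for label in ordering]
    if any(len(s) == 0 for s in sets):
        raise ValidationError("every construct needs at least one term")
    months = sets[0][0].months
    for s in sets:
        for t in s:
            if not t.months.equals(months):
                raise ValidationError(f"term '{t.term}' does not cover the common month range")

    rows = []
    for combo in product(*sets):
        names = tuple(t.term for t in combo)
        values = np.column_stack([np.log(t.values + log_offset) for t in combo])
        try:
            panel = Panel(values, months[0], ordering)
            sfit = identify_structural(fit_reduced(panel))
            rows.append(
                GridRow(names, sfit.params.beta21, sfit.params.beta31, sfit.params.beta32)
            )
        except ValidationError as exc:
            rows.append(GridRow(names, status="failed", reason=str(exc)))
    return GridResult(ordering=ordering, rows=rows)


def summarize_grid(grid: GridResult, near_zero_tol: float = 0.05) -> pd.DataFrame:
    """Per-relationship sign counts and spread across the grid's submodels."""
    if not grid.rows:
        raise ValidationError("empty grid")
    betas = grid.betas
    out = []
    for name, col in zip(("beta21", "beta31", "beta32"), betas.T):
        col = col[np.isfinite(col)]
        out.append(
            {
                "relationship": name,
                "n": len(col),
                "n_positive": int(np.sum(col > 0)),
                "n_negative": int(np.sum(col < 0)),
                "n_near_zero": int(np.sum(np.abs(col) <= near_zero_tol)),
                "min": col.min() if len(col) else np.nan,
                "median": float(np.median(col)) if len(col) else np.nan,
                "max": col.max() if len(col) else np.nan,
            }
        )
    return pd.DataFrame(out)
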