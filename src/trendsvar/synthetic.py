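"""Synthetic search-interest panels with known SVAR(1) ground truth.

The generator is the generative reading of the structural system: draw
independent Gaussian shocks ``e_t`` with SDs ``shock_scales``, propagate

    x_t = c + d * t + B x_{t-1} + L e_t,

and optionally post-process back onto the Google-Trends presentation
(0-100 integer indices, maximum pinned at 100, event-month spikes at the
dates of named violent attacks).  Simulation starts from the deterministic
steady level ``(I - B)^{-1} c`` and discards a burn-in, so the returned
sample is free of initialisation transients.  The default study
conditions mirror the real extracts: T = 168 months from 2004-01, five
event spikes, five search terms per construct.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import StabilityError, ValidationError
from .ingest import TermSeries
from .types import Panel, StructuralParams, spectral_radius

DEFAULT_START = "2004-01"
DEFAULT_N_MONTHS = 168
DEFAULT_BURN_IN = 100

#: Stylised informational-shock events (log-interest spike added per
#: variable).  Dates are the attacks whose months dominate the real
#: series: Sandy Hook, Boston Marathon, San Bernardino, Orlando,
#: Las Vegas.  Magnitudes are largest for violent-attack interest, with
#: gun-control interest spiking hardest after Sandy Hook/Boston and
#: gun-purchase interest after Sandy Hook/San Bernardino.
DEFAULT_EVENTS = (
    ("2012-12", (1.2, 1.0, 0.8)),
    ("2013-04", (0.9, 0.7, 0.2)),
    ("2015-12", (0.8, 0.3, 0.7)),
    ("2016-06", (1.1, 0.4, 0.3)),
    ("2017-10", (1.2, 0.3, 0.2)),
)


def simulate_svar(
    params: StructuralParams,
    n_months: int = DEFAULT_N_MONTHS,
    burn_in: int = DEFAULT_BURN_IN,
    seed: Optional[int] = None,
    start_month: str = DEFAULT_START,
) -> Panel:
    """Simulate a log-scale panel from the structural VAR(1).

    The trend index runs 1..n_months over the returned sample; during
    burn-in the deterministic part is held at its t=0 level so the
    retained sample starts on-trend.  Identical seed and parameters give
    bit-identical panels.
    """
    if n_months < 1:
        raise ValidationError("n_months must be >= 1")
    if burn_in < 0:
        raise ValidationError("burn_in must be >= 0")
    rho = spectral_radius(params.lag_matrix)
    if rho >= 1.0:
        raise StabilityError(
            f"lag matrix is not stable: spectral radius {rho:.3f} >= 1"
        )
    k = params.n_vars
    b = params.lag_matrix
    impact = params.impact
    c = impact @ params.alpha
    d = impact @ params.mu

    rng = np.random.default_rng(seed)
    shocks = rng.standard_normal((burn_in + n_months, k)) * params.shock_scales
    x = np.linalg.solve(np.eye(k) - b, c)  # deterministic steady level at t=0
    out = np.empty((n_months, k))
    for s in range(burn_in + n_months):
        t = max(s + 1 - burn_in, 0)
        x = c + d * t + b @ x + impact @ shocks[s]
        if s >= burn_in:
            out[s - burn_in] = x
    return Panel(out, pd.Period(start_month, freq="M"), params.labels)


def inject_event_spikes(panel: Panel, events: Sequence[tuple]) -> Panel:
    """Add event-month spikes; returns a copy, other cells untouched.

    ``events`` is a sequence of ``(month, magnitudes)`` pairs with
    magnitudes in log-interest units, one per variable.
    """
    values = panel.values.copy()
    for month, mags in events:
        mags = np.asarray(mags, dtype=float)
        if mags.shape != (panel.n_vars,) or not np.all(np.isfinite(mags)):
            raise ValidationError(f"event {month}: need {panel.n_vars} finite magnitudes")
        values[panel.month_offset(month)] += mags
    return Panel(values, panel.start_month, panel.columns)


def to_trends_scale(raw: np.ndarray) -> np.ndarray:
    """Rescale a nonnegative series onto the 0-100 integer index.

    Output is ``round(100 * x / max(x))`` so the series maximum is 100,
    matching the common-upper-bound normalisation of search indices.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValidationError("series must be nonnegative")
    m = raw.max(initial=0.0)
    if m <= 0:
        raise ValidationError("all-zero series has no defined maximum")
    return np.rint(100.0 * raw / m).astype(int)


def panel_to_interest(panel: Panel, log_offset: float = 1.0) -> np.ndarray:
    """Invert the log transform back to interest scale, exp(x) - offset, floored at 0."""
    return np.maximum(np.exp(panel.values) - log_offset, 0.0)


def simulate_term_sets(
    params: StructuralParams,
    terms_per_construct: int = 5,
    n_months: int = DEFAULT_N_MONTHS,
    seed: Optional[int] = None,
    term_noise_sd: float = 0.15,
    events: Sequence[tuple] = DEFAULT_EVENTS,
    start_month: str = DEFAULT_START,
) -> dict[str, list[TermSeries]]:
    """Per-construct sets of single search-term series with shared truth.

    Each term is its construct's latent log series plus independent
    Gaussian measurement noise (SD ``term_noise_sd`` log units, emulating
    term-specific wording and sampling variation), mapped back to the
    0-100 integer index.  Returns ``{label: [TermSeries, ...]}``.
    """
    rng = np.random.default_rng(seed)
    panel = simulate_svar(
        params, n_months=n_months, seed=rng.integers(2**31), start_month=start_month
    )
    if events:
        # default event dates assume the full 2004-2017 window; on shorter
        # panels only the events inside the simulated range apply
        in_range = [
            ev for ev in events
            if 0 <= (pd.Period(ev[0], freq="M") - panel.start_month).n < panel.n_obs
        ]
        panel = inject_event_spikes(panel, in_range)
    months = panel.months
    sets: dict[str, list[TermSeries]] = {}
    for j, label in enumerate(panel.columns):
        terms = []
        for i in range(terms_per_construct):
            noisy = panel.values[:, j] + rng.normal(0.0, term_noise_sd, size=panel.n_obs)
            interest = np.maximum(np.exp(noisy) - 1.0, 0.0)
            terms.append(
                TermSeries(
                    term=f"{label.lower()}_term_{i + 1}",
                    months=months,
                    values=to_trends_scale(interest).astype(float),
                )
            )
        sets[label] = terms
    return sets


def write_trends_csv(terms: Sequence[TermSeries], path) -> None:
    """Write term series in the Trends multiTimeline CSV dialect.

    Preamble line, blank line, ``Month,<term>...`` header, then
    ``YYYY-MM,<int>...`` rows.  Values are written as integers; the
    reader reproduces them exactly.
    """
    if not terms:
        raise ValidationError("need at least one term series")
    months = terms[0].months
    for t in terms[1:]:
        if not t.months.equals(months):
            raise ValidationError("all term series must share the same months")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        fh.write("Category: All categories\n\n")
        writer.writerow(["Month"] + [t.term for t in terms])
        for i, month in enumerate(months):
            writer.writerow([str(month)] + [format(t.values[i], "g") for t in terms])
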