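"""Reading Trends-dialect CSVs and building the composite analysis panel.

The input dialect is the "multiTimeline" export: optional preamble lines
(e.g. ``Category: All categories``), a blank line, a ``Month,<term>...``
header, then one row per month ``YYYY-MM,<int>...``.  Cells censored
below one are exported as ``"<1"`` and read back as 0.5, the midpoint of
the censored interval.

A composite construct (VA, GC, GP) is the per-month sum of its
jointly-scaled term series, rescaled so the composite maximum is 100 --
an offline approximation to a joint query normalised on the largest term.
The analysis panel is ``ln(composite + 1)`` with columns in Wold causal
order; the +1 offset keeps zero-interest months finite.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import DEFAULT_LABELS, Panel


@dataclass
class TermSeries:
    """One search term's monthly 0-100 interest index."""

    term: str
    months: pd.PeriodIndex
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.months = pd.PeriodIndex(self.months, freq="M")
        if len(self.months) != len(self.values):
            raise ValidationError(f"term '{self.term}': months/values length mismatch")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValidationError(f"term '{self.term}': values must lie in [0, 100]")
        _check_contiguous(self.months)


@dataclass
class CompositeSeries:
    """Construct-level 0-100 composite built from several terms."""

    construct: str
    months: pd.PeriodIndex
    values: np.ndarray
    source_terms: tuple[str, ...]


def _check_contiguous(months: pd.PeriodIndex) -> None:
    steps = (months[1:] - months[:-1]).map(lambda d: d.n)
    for i, step in enumerate(steps):
        if step == 0:
            raise FormatError(f"duplicated month {months[i + 1]}")
        if step < 0:
            raise FormatError(f"months not increasing at {months[i + 1]}")
        if step > 1:
            raise FormatError(f"missing month {months[i] + 1}")


def _parse_cell(cell: str, month: str, term: str) -> float:
    cell = cell.strip()
    if cell == "<1":
        return 0.5  # censored below 1; midpoint of the interval
    try:
        return float(cell)
    except ValueError:
        raise FormatError(
            f"non-numeric cell '{cell}' for term '{term}' in row {month}"
        ) from None


def read_trends_csv(path) -> list[TermSeries]:
    """Parse a multiTimeline-dialect CSV into one TermSeries per column."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh)]

    header_idx = None
    for i, row in enumerate(rows):
        if row and row[0].strip().lower() == "month":
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(f"{path}: no 'Month' header row found")
    header = [c.strip() for c in rows[header_idx]]
    terms = header[1:]
    if not terms:
        raise FormatError(f"{path}: header has no term columns")

    months, data = [], []
    for row in rows[header_idx + 1 :]:
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise FormatError(f"{path}: row '{','.join(row)}' has wrong column count")
        try:
            months.append(pd.Period(row[0].strip(), freq="M"))
        except Exception:
            raise FormatError(f"{path}: bad month '{row[0]}'") from None
        data.append([_parse_cell(c, row[0], t) for c, t in zip(row[1:], terms)])
    if not months:
        raise FormatError(f"{path}: no data rows")
    idx = pd.PeriodIndex(months, freq="M")
    _check_contiguous(idx)
    values = np.asarray(data, dtype=float)
    return [TermSeries(term=t, months=idx, values=values[:, j]) for j, t in enumerate(terms)]


def build_composite(terms: Sequence[TermSeries], construct: str) -> CompositeSeries:
    """Sum jointly-scaled terms per month, rescale so the maximum is 100."""
    if not terms:
        raise ValidationError("composite needs at least one term")
    months = terms[0].months
    for t in terms[1:]:
        if len(t.months) != len(months) or not t.months.equals(months):
            raise ValidationError(
                f"term '{t.term}' months differ from '{terms[0].term}'"
            )
    total = np.sum([t.values for t in terms], axis=0)
    m = total.max(initial=0.0)
    if m <= 0:
        raise ValidationError(f"composite '{construct}' is identically zero")
    return CompositeSeries(
        construct=construct,
        months=months,
        values=100.0 * total / m,
        source_terms=tuple(t.term for t in terms),
    )


def log_panel(
    composites: Sequence[CompositeSeries],
    ordering: Sequence[str] = DEFAULT_LABELS,
    log_offset: float = 1.0,
) -> Panel:
    """Assemble the log-scale panel, columns in the configured causal order."""
    ordering = tuple(ordering)
    got = tuple(c.construct for c in composites)
    if len(got) != len(ordering):
        raise ValidationError(f"expected {len(ordering)} composites, got {len(got)}")
    if got != ordering:
        raise ValidationError(f"composites must be supplied in order {ordering}, got {got}")
    months = composites[0].months
    for c in composites[1:]:
        if not c.months.equals(months):
            raise ValidationError("composites must share a common month range")
    values = np.column_stack([np.log(c.values + log_offset) for c in composites])
    return Panel(values, months[0], ordering)
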