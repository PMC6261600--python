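"""Core containers: structural parameters and the analysis panel.

The model is a structural VAR(1) with a recursive (Wold) contemporaneous
ordering,

    A0 x_t = alpha + mu * t + A1 x_{t-1} + e_t,

where ``A0`` is unit lower triangular, ``e_t`` has independent Gaussian
components with standard deviations ``shock_scales``, and ``t`` is a linear
monthly trend index running 1..T.  Solving for ``x_t`` gives the reduced
form

    x_t = c + d * t + B x_{t-1} + u_t,      u_t = L e_t,  L = A0^{-1},

with ``c = L alpha``, ``d = L mu`` and ``B = L A1``.  Throughout the package
``lag_matrix`` stores the *reduced-form* ``B`` (the matrix least squares
estimates directly), not the structural ``A1``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_LABELS = ("VA", "GC", "GP")


def beta_matrix_from_triple(beta21: float, beta31: float, beta32: float) -> np.ndarray:
    """Strictly-lower-triangular 3x3 contemporaneous coefficient matrix."""
    b = np.zeros((3, 3))
    b[1, 0] = beta21
    b[2, 0] = beta31
    b[2, 1] = beta32
    return b


def spectral_radius(m: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(m, dtype=float)))))


@dataclass(frozen=True)
class StructuralParams:
    """Parameters of the structural VAR(1).

    Attributes
    ----------
    alpha
        Per-equation structural level, log-interest units.
    mu
        Per-equation linear trend slope, log-interest units per month.
    beta
        Strictly-lower-triangular contemporaneous coefficients; entry
        ``beta[i, j]`` is the same-month effect of variable ``j`` on
        variable ``i`` (for K=3 these are beta21, beta31, beta32).
    lag_matrix
        Reduced-form first-order lag matrix ``B`` (x_t on x_{t-1}).
    shock_scales
        Standard deviations of the structural innovations, strictly
        positive, log-interest units.
    labels
        Variable names in Wold causal order.
    """

    alpha: np.ndarray
    mu: np.ndarray
    beta: np.ndarray
    lag_matrix: np.ndarray
    shock_scales: np.ndarray
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        for name in ("alpha", "mu", "beta", "lag_matrix", "shock_scales"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        k = self.alpha.shape[0]
        if self.mu.shape != (k,) or self.shock_scales.shape != (k,):
            raise ValidationError("alpha, mu and shock_scales must share length K")
        if self.beta.shape != (k, k) or self.lag_matrix.shape != (k, k):
            raise ValidationError("beta and lag_matrix must be K x K")
        if np.any(np.triu(self.beta) != 0):
            raise ValidationError("beta must be strictly lower triangular")
        if np.any(self.shock_scales <= 0):
            raise ValidationError("shock_scales must be strictly positive")
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != k:
            raise ValidationError("labels must match the number of variables")

    @property
    def n_vars(self) -> int:
        return self.alpha.shape[0]

    @property
    def a0(self) -> np.ndarray:
        """Unit-lower-triangular contemporaneous matrix A0 = I - beta."""
        return np.eye(self.n_vars) - self.beta

    @property
    def impact(self) -> np.ndarray:
        """L = A0^{-1}: maps structural shocks to reduced-form innovations."""
        return np.linalg.inv(self.a0)

    @property
    def beta21(self) -> float:
        return float(self.beta[1, 0])

    @property
    def beta31(self) -> float:
        return float(self.beta[2, 0])

    @property
    def beta32(self) -> float:
        return float(self.beta[2, 1])

    @property
    def stable(self) -> bool:
        return spectral_radius(self.lag_matrix) < 1.0


@dataclass
class Panel:
    """T x K matrix of log-scale interest series in Wold causal order.

    Column order is meaningful: it defines the recursive identification
    ordering used downstream.
    """

    values: np.ndarray
    start_month: pd.Period
    columns: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("panel values must be finite")
        if isinstance(self.start_month, str):
            self.start_month = pd.Period(self.start_month, freq="M")
        self.columns = tuple(self.columns)
        if self.values.shape[1] != len(self.columns):
            raise ValidationError("number of columns must match column labels")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=self.n_obs, freq="M")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.months, columns=list(self.columns))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Panel":
        idx = pd.PeriodIndex(frame.index, freq="M")
        if len(idx) > 1 and not (idx[1:] - idx[:-1] == 1).all():
            raise ValidationError("panel months must be contiguous")
        return cls(frame.to_numpy(dtype=float), idx[0], tuple(frame.columns))

    def month_offset(self, month) -> int:
        """Row index of a calendar month; raises if outside the panel."""
        p = pd.Period(month, freq="M")
        off = (p - self.start_month).n
        if not 0 <= off < self.n_obs:
            raise ValidationError(
                f"month {p} outside panel range {self.start_month}..{self.months[-1]}"
            )
        return off
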