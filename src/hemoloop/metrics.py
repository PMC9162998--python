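"""Controller performance statistics.

The loop is scored with the Varvel-style indices standard for closed-loop
drug delivery.  The performance error at sample t is

    PE(t) = (Variable(t) - Target(t)) / Variable(t) * 100   [%]

(the measured variable in the denominator), and the summaries are

    MDPE       = median{PE(t)}              bias
    MDAPE      = median{|PE(t)|}            accuracy
    wobble     = median{|PE(t) - MDPE|}     stability
    divergence = OLS slope of |PE| vs t     trend, %/min

computed over a scoring window (default 15-60 min, skipping the settling
transient).  Safety is additionally scored as the percentage of time a
signal stays within a one-sided acceptable band around its target: AP no
more than 5 mmHg below AP*, P_LA no more than 2 mmHg above P_LA*, boundary
inclusive, over the full control period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PESeries",
    "MetricsReport",
    "performance_error",
    "pe_series",
    "mdpe",
    "mdape",
    "wobble",
    "divergence",
    "time_in_acceptable_range",
    "summarize",
    "PE_WINDOW",
    "AP_MARGIN",
    "P_LA_MARGIN",
]

#: Default PE scoring window (min): hemodynamics settle within ~15 min.
PE_WINDOW: tuple[float, float] = (15.0, 60.0)
#: Acceptable-range margins (mmHg): AP at or above AP*-5, P_LA at or below P_LA*+2.
AP_MARGIN = 5.0
P_LA_MARGIN = 2.0

_EPS = 1e-9  # window-edge tolerance for float time grids


@dataclass(frozen=True)
class PESeries:
    """Performance-error series for one controlled signal."""

    t: np.ndarray  # sample times, min, strictly increasing
    pe: np.ndarray  # PE, %
    variable_name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        pe = np.asarray(self.pe, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pe", pe)
        if t.shape != pe.shape or t.ndim != 1:
            raise ValueError("t and pe must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.all(np.isfinite(pe)):
            raise ValueError("PE must be finite at every sample")

    def in_window(self, window: tuple[float, float] | None) -> "PESeries":
        """Restrict to t in [start, end], boundaries inclusive."""
        if window is None:
            return self
        start, end = window
        mask = (self.t >= start - _EPS) & (self.t <= end + _EPS)
        if not mask.any():
            raise ValueError(f"no samples in window [{start}, {end}] min")
        return PESeries(self.t[mask], self.pe[mask], self.variable_name)


@dataclass(frozen=True)
class MetricsReport:
    """Summary statistics for one signal over a scoring window."""

    variable_name: str
    MDPE: float  # %
    MDAPE: float  # %
    wobble: float  # %
    divergence: float  # %/min
    time_in_range: float  # %
    window: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "variable": self.variable_name,
            "MDPE_pct": self.MDPE,
            "MDAPE_pct": self.MDAPE,
            "wobble_pct": self.wobble,
            "divergence_pct_per_min": self.divergence,
            "time_in_range_pct": self.time_in_range,
            "window_min": list(self.window),
        }


def performance_error(value: float | np.ndarray, target: float | np.ndarray):
    """PE = (value - target)/value * 100, with the measured value as denominator."""
    value = np.asarray(value, dtype=float)
    if np.any(value == 0):
        raise ZeroDivisionError("PE undefined where the measured variable is 0")
    out = (value - np.asarray(target, dtype=float)) / value * 100.0
    return float(out) if out.ndim == 0 else out


def pe_series(
    t: Sequence[float],
    values: Sequence[float],
    target: float,
    variable_name: str = "",
) -> PESeries:
    """Build a :class:`PESeries` from a measured signal and a constant target."""
    return PESeries(
        np.asarray(t, dtype=float),
        performance_error(np.asarray(values, dtype=float), target),
        variable_name,
    )


def mdpe(pe: PESeries, window: tuple[float, float] | None = PE_WINDOW) -> float:
    """Median PE (bias, %). Even-length median is the mean of the middle pair."""
    return float(np.median(pe.in_window(window).pe))


def mdape(pe: PESeries, window: tuple[float, float] | None = PE_WINDOW) -> float:
    """Median absolute PE (accuracy, %)."""
    return float(np.median(np.abs(pe.in_window(window).pe)))


def wobble(pe: PESeries, window: tuple[float, float] | None = PE_WINDOW) -> float:
    """Median |PE - MDPE| (stability, %), with MDPE from the same window."""
    w = pe.in_window(window).pe
    return float(np.median(np.abs(w - np.median(w))))


def divergence(pe: PESeries, window: tuple[float, float] | None = PE_WINDOW) -> float:
    """OLS slope of |PE(t)| against t in minutes (trend, %/min)."""
    sub = pe.in_window(window)
    t = sub.t
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("divergence needs >= 2 distinct time points")
    y = np.abs(sub.pe)
    dt_ = t - t.mean()
    return float(np.dot(dt_, y - y.mean()) / np.dot(dt_, dt_))


def time_in_acceptable_range(
    values: Sequence[float],
    target: float,
    side: Literal["lower_bound", "upper_bound"],
    margin: float,
) -> float:
    """Percent of samples inside the one-sided band, boundary inclusive.

    ``lower_bound``: value >= target - margin (AP safety band, margin 5 mmHg).
    ``upper_bound``: value <= target + margin (P_LA congestion band, 2 mmHg).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one sample")
    if side == "lower_bound":
        ok = v >= target - margin
    elif side == "upper_bound":
        ok = v <= target + margin
    else:
        raise ValueError(f"side must be 'lower_bound' or 'upper_bound', got {side!r}")
    return float(ok.mean() * 100.0)


def summarize(
    t: Sequence[float],
    values: Sequence[float],
    target: float,
    variable_name: str,
    side: Literal["lower_bound", "upper_bound"],
    margin: float,
    window: tuple[float, float] = PE_WINDOW,
) -> MetricsReport:
    """Full report for one signal: PE statistics on ``window``, time-in-range
    over all supplied samples (the full control period by default)."""
    pe = pe_series(t, values, target, variable_name)
    return MetricsReport(
        variable_name=variable_name,
        MDPE=mdpe(pe, window),
        MDAPE=mdape(pe, window),
        wobble=wobble(pe, window),
        divergence=divergence(pe, window),
        time_in_range=time_in_acceptable_range(values, target, side, margin),
        window=window,
    )
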