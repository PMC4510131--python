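"""Offline analysis of calibration data and experiment logs.

Three groups of computations:

* calibration regressions — ordinary least squares with explicit
  exclusion windows (transmittance vs log cell density restricted to the
  exponential-phase window; transmittance vs pH restricted to the
  indicator's linear window; flow rate vs pinch time);
* growth-rate and generation accounting — the specific growth rate from
  a refresh-free batch stretch, and the cumulative number of population
  doublings of a continuous culture from its dilution events;
* steady-state summaries — box-whisker statistics (median, quartiles by
  linear interpolation, 1.5*IQR whiskers clipped to the data).

Exclusion windows are parameters, never hard-coded: which points belong
to the exponential phase or the indicator's linear range is an
organism-specific judgment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, FitError, StateError
from .logio import ExperimentLog
from .optics import absorbance_from_transmittance

__all__ = [
    "LinearFit",
    "SteadyStateSummary",
    "GenerationEstimate",
    "linear_fit",
    "fit_transmittance_vs_logcfu",
    "fit_transmittance_vs_pH",
    "fit_flow_calibration",
    "estimate_growth_rate",
    "generations_from_log",
    "steady_state_summary",
]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with its Pearson correlation."""

    slope: float
    intercept: float
    r: float
    r2: float
    n_used: int
    n_excluded: int = 0

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class SteadyStateSummary:
    """Box-whisker statistics of a steady-state stretch."""

    median: float
    Q1: float
    Q3: float
    whisker_low: float
    whisker_high: float
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class GenerationEstimate:
    """Population doublings over a log, from dilution bookkeeping.

    At steady state, dilution exactly balances growth, so generations
    equal the cumulative dilution factor in log2. If the log is not
    steady (start and end transmittance differ), the net change in cell
    density is added as ``log2`` of the absorbance ratio (turbidity
    readout only) and ``corrected`` is set.
    """

    generations: float
    dilution_doublings: float
    corrected: bool


def linear_fit(xs, ys, n_excluded: int = 0) -> LinearFit:
    """OLS fit of ``ys`` against ``xs`` with Pearson r.

    A constant ``ys`` yields slope 0 and r = 0; a degenerate ``xs``
    (fewer than two distinct values) raises :class:`FitError`.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise FitError("xs and ys must be 1-D and equal length")
    if len(xs) < 2 or np.ptp(xs) == 0:
        raise FitError("need at least 2 distinct x values")
    if np.ptp(ys) == 0:
        return LinearFit(0.0, float(ys[0]), 0.0, 0.0, len(xs), n_excluded)
    res = stats.linregress(xs, ys)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        n_used=len(xs),
        n_excluded=n_excluded,
    )


def _windowed_fit(T, x, keep) -> LinearFit:
    keep = np.asarray(keep, dtype=bool)
    if not keep.any():
        raise FitError("all points fall outside the fit window")
    return linear_fit(
        np.asarray(x, dtype=float)[keep],
        np.asarray(T, dtype=float)[keep],
        n_excluded=int((~keep).sum()),
    )


def fit_transmittance_vs_logcfu(points, T_range: tuple[float, float]) -> LinearFit:
    """Fit transmittance against log10 cell density inside a T window.

    ``points`` are (transmittance %, CFU/mL) pairs; points whose
    transmittance lies outside ``T_range`` (typically the
    exponential-phase interval, e.g. 25–70 %) are excluded and counted.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be (T, CFU) pairs")
    T, cfu = pts[:, 0], pts[:, 1]
    if np.any(cfu <= 0):
        raise FitError("cell densities must be > 0 for a log fit")
    lo, hi = T_range
    return _windowed_fit(T, np.log10(cfu), (T >= lo) & (T <= hi))


def fit_transmittance_vs_pH(points, window: tuple[float, float] = (6.0, 7.0)) -> LinearFit:
    """Fit transmittance against pH inside the indicator's linear window."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be (T, pH) pairs")
    T, pH = pts[:, 0], pts[:, 1]
    lo, hi = window
    return _windowed_fit(T, pH, (pH >= lo) & (pH <= hi))


def fit_flow_calibration(points) -> LinearFit:
    """Fit delivered volume (mL) against pinch time (s).

    The slope estimates the flow rate; a positive x-intercept estimates
    the dead time of the tubing.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be (pinch_time, volume) pairs")
    return linear_fit(pts[:, 0], pts[:, 1])


def estimate_growth_rate(log: ExperimentLog, interval: tuple[float, float]) -> float:
    """Specific growth rate (per hour) from a refresh-free batch stretch.

    For a turbidity readout, absorbance is proportional to cell density,
    so the slope of ``ln A`` against time is the specific growth rate.
    ``interval`` is (start, end) in seconds of log time and must not
    span any refresh event.
    """
    t0, t1 = interval
    if not t1 > t0:
        raise DomainError("interval must satisfy t1 > t0")
    ev = log.refresh_cycles
    if len(ev) and ((ev["time_s"] >= t0) & (ev["time_s"] <= t1)).any():
        raise StateError("growth-rate interval must not span refresh events")
    s = log.samples
    sel = s[(s["time_s"] >= t0) & (s["time_s"] <= t1)]
    if len(sel) < 2:
        raise FitError("need at least 2 samples in the interval")
    A = absorbance_from_transmittance(sel["filtered_pct"].to_numpy())
    if np.any(A <= 0):
        raise DomainError("absorbance must be positive over the interval (T < 100%)")
    fit = linear_fit(sel["time_s"].to_numpy() / 3600.0, np.log(A))
    return fit.slope


def generations_from_log(
    log: ExperimentLog,
    working_volume: float | None = None,
    steady_tol_pct: float = 1.0,
) -> GenerationEstimate:
    """Cumulative population doublings over a continuous-culture log.

    Sums ``log2((w + v) / w)`` over refresh events. If the start and end
    filtered transmittance differ by more than ``steady_tol_pct``
    percentage points, the net growth term ``log2(A_end / A_start)`` is
    added (turbidity polarity only, where absorbance tracks density) and
    the estimate is flagged as corrected.
    """
    if working_volume is None:
        try:
            working_volume = log.metadata["config"]["vessel"]["working_volume"]
        except (KeyError, TypeError):
            raise DomainError(
                "working_volume not found in log metadata; pass it explicitly"
            ) from None
    w = float(working_volume)
    added = log.refresh_cycles["volume_added_mL"].to_numpy()
    dilution = float(np.sum(np.log2((w + added) / w))) if len(added) else 0.0

    s = log.samples
    if len(s) < 2:
        return GenerationEstimate(dilution, dilution, corrected=False)
    T_start = float(s["filtered_pct"].iloc[0])
    T_end = float(s["filtered_pct"].iloc[-1])
    if abs(T_end - T_start) <= steady_tol_pct:
        return GenerationEstimate(dilution, dilution, corrected=False)
    polarity = None
    try:
        polarity = log.metadata["config"]["polarity"]
    except (KeyError, TypeError):
        pass
    if polarity == "growth_increases_T":
        # phenol-red readout: absorbance is not proportional to density,
        # so no end-state correction can be computed from T alone.
        return GenerationEstimate(dilution, dilution, corrected=True)
    correction = math.log2(
        absorbance_from_transmittance(T_end) / absorbance_from_transmittance(T_start)
    )
    return GenerationEstimate(dilution + correction, dilution, corrected=True)


def steady_state_summary(values, times=None, window=None) -> SteadyStateSummary:
    """Box-whisker summary: median, quartiles, 1.5*IQR whiskers.

    Quartiles use linear interpolation between order statistics.
    Whiskers extend to the most extreme data point within 1.5 IQR of the
    quartiles, so they always lie inside [min, max]. Optionally restrict
    to samples whose ``times`` fall inside ``window``.
    """
    values = np.asarray(values, dtype=float)
    if window is not None:
        if times is None:
            raise DomainError("a window requires matching times")
        times = np.asarray(times, dtype=float)
        values = values[(times >= window[0]) & (times <= window[1])]
    if len(values) < 4:
        raise DomainError("need at least 4 samples for a box-whisker summary")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return SteadyStateSummary(
        median=float(med),
        Q1=float(q1),
        Q3=float(q3),
        # whiskers reach the most extreme point inside the fences but never
        # retreat inside the (interpolated) box
        whisker_low=float(min(values[values >= lo_fence].min(), q1)),
        whisker_high=float(max(values[values <= hi_fence].max(), q3)),
        min=float(values.min()),
        max=float(values.max()),
        n=len(values),
    )
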