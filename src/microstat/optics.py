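"""Optical signal chain for continuous-culture monitoring.

The rig measures growth through a 560 nm LED / photoreceiver pair. Two
readouts exist:

* **turbidity** — cells scatter and absorb light, so transmittance falls
  as the population grows (Beer-Lambert: absorbance linear in cell
  density);
* **phenol red** — very small cells (mollicutes) barely scatter light,
  but their metabolism acidifies the medium; phenol red absorbs less at
  560 nm as pH drops, so transmittance *rises* with growth.

This module converts between raw detector signal, percent transmittance
and absorbance, models both readouts, and implements the acquisition
chain (sampling, boxcar averaging, additive detector noise). Relative
transmittance is defined by a two-point calibration: a *dark* reading
(total obscurity, 0 %) and a *blank* reading (cell-free medium or water,
100 %).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, StateError

__all__ = [
    "CalibrationRecord",
    "AcquisitionSettings",
    "OpticalModelParams",
    "SignalTrace",
    "CalibratedReading",
    "BoxcarStream",
    "raw_to_transmittance",
    "absorbance_from_transmittance",
    "cell_absorbance",
    "phenolred_absorbance",
    "transmittance_from_components",
    "boxcar_filter",
    "sample_measurement",
]

#: The LED/photoreceiver pair operates at a fixed wavelength.
WAVELENGTH_NM = 560.0


@dataclass(frozen=True)
class CalibrationRecord:
    """Two-point detector calibration defining relative transmittance.

    Parameters
    ----------
    dark_signal:
        Raw detector reading under total obscurity; defines 0 % T.
    blank_signal:
        Raw detector reading through the cell-free reference liquid
        (medium or water); defines 100 % T.
    wavelength:
        Carried as metadata; the hardware is fixed at 560 nm.
    label:
        Free-text tag (e.g. which reference liquid was used).
    """

    dark_signal: float
    blank_signal: float
    wavelength: float = WAVELENGTH_NM
    label: str = ""

    def __post_init__(self) -> None:
        if not self.blank_signal > self.dark_signal:
            raise ConfigurationError(
                "calibration requires blank_signal > dark_signal "
                f"(got blank={self.blank_signal}, dark={self.dark_signal})"
            )
        if self.wavelength != WAVELENGTH_NM:
            raise ConfigurationError(
                f"wavelength is fixed at {WAVELENGTH_NM} nm (got {self.wavelength})"
            )

    @property
    def span(self) -> float:
        """Raw-signal difference between blank and dark."""
        return self.blank_signal - self.dark_signal


@dataclass(frozen=True)
class AcquisitionSettings:
    """Sampling parameters of the detector read-out.

    ``sample_period`` is in seconds, ``n_average`` is the length of the
    moving boxcar window applied to calibrated transmittance, and
    ``noise_sd`` is the standard deviation of additive Gaussian detector
    noise *in raw-signal units* (0 disables noise).
    """

    sample_period: float = 5.0
    n_average: int = 1
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_period > 0:
            raise ConfigurationError("sample_period must be > 0")
        if self.n_average < 1:
            raise ConfigurationError("n_average must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class OpticalModelParams:
    """Forward model linking culture state to 560 nm absorbance.

    ``k_cell`` is the absorbance contributed per (CFU/mL) per cm of path
    (turbidity, Beer-Lambert). The phenol-red term is piecewise linear in
    pH: ``phenolred_A_min`` at/below ``pH_lo``, ``phenolred_A_max``
    at/above ``pH_hi``, linear in between. Behaviour outside the window
    is deliberately flat — the indicator's response was only observed to
    be linear over roughly pH 6–7.
    """

    k_cell: float = 0.0
    path_length: float = 1.0
    phenolred_A_min: float = 0.0
    phenolred_A_max: float = 0.0
    pH_lo: float = 6.0
    pH_hi: float = 7.0

    def __post_init__(self) -> None:
        if self.k_cell < 0:
            raise ConfigurationError("k_cell must be >= 0")
        if not self.path_length > 0:
            raise ConfigurationError("path_length must be > 0")
        if not (self.phenolred_A_max >= self.phenolred_A_min >= 0):
            raise ConfigurationError("require phenolred_A_max >= phenolred_A_min >= 0")
        if not self.pH_hi > self.pH_lo:
            raise ConfigurationError("require pH_hi > pH_lo")


@dataclass
class SignalTrace:
    """An ordered (time, value) series with strictly increasing times."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ConfigurationError("times and values must be 1-D and equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("times must be strictly increasing")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "SignalTrace":
        pairs = list(pairs)
        if not pairs:
            return cls(np.empty(0), np.empty(0))
        t, v = zip(*pairs)
        return cls(np.asarray(t), np.asarray(v))

    def __len__(self) -> int:
        return len(self.times)


class CalibratedReading(NamedTuple):
    """A calibrated transmittance with its out-of-range flag.

    Values below 0 % or above 100 % are *not* clipped — they indicate
    calibration drift (or a brighter-than-blank liquid) and are returned
    unmodified with ``out_of_range`` set.
    """

    percent: float
    out_of_range: bool


def raw_to_transmittance(raw, calib: CalibrationRecord) -> CalibratedReading:
    """Convert a raw detector signal to percent relative transmittance.

    ``T = 100 * (raw - dark) / (blank - dark)``; affine and
    order-preserving in the raw signal. Accepts scalars or arrays.
    """
    raw = np.asarray(raw, dtype=float)
    pct = 100.0 * (raw - calib.dark_signal) / calib.span
    oor = (pct < 0.0) | (pct > 100.0)
    if pct.ndim == 0:
        return CalibratedReading(float(pct), bool(oor))
    return CalibratedReading(pct, oor)


def absorbance_from_transmittance(T):
    """Absorbance (optical density) from percent transmittance.

    ``A = -log10(T / 100)``. ``T <= 0`` has no absorbance equivalent and
    raises :class:`DomainError`.
    """
    arr = np.asarray(T, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("transmittance must be > 0 to convert to absorbance")
    out = -np.log10(arr / 100.0)
    return float(out) if out.ndim == 0 else out


def cell_absorbance(X: float, params: OpticalModelParams) -> float:
    """Turbidity absorbance of a cell suspension, linear in density.

    ``A = k_cell * X * path_length`` with X in CFU/mL.
    """
    if X < 0:
        raise StateError(f"cell density must be >= 0 (got {X})")
    return params.k_cell * X * params.path_length


def phenolred_absorbance(pH, params: OpticalModelParams):
    """560 nm absorbance of phenol-red medium at a given pH.

    Piecewise linear with flat saturation: ``phenolred_A_min`` at/below
    ``pH_lo``, ``phenolred_A_max`` at/above ``pH_hi``, linear between.
    Monotone non-decreasing in pH.
    """
    pH = np.asarray(pH, dtype=float)
    frac = np.clip((pH - params.pH_lo) / (params.pH_hi - params.pH_lo), 0.0, 1.0)
    out = params.phenolred_A_min + frac * (params.phenolred_A_max - params.phenolred_A_min)
    return float(out) if out.ndim == 0 else out


def transmittance_from_components(A_cells: float, A_medium: float) -> float:
    """Percent transmittance from additive absorbance contributions.

    Beer-Lambert closure: ``T = 100 * 10**-(A_cells + A_medium)``.
    """
    if A_cells < 0 or A_medium < 0:
        raise DomainError("absorbance components must be >= 0")
    return 100.0 * 10.0 ** (-(A_cells + A_medium))


def boxcar_filter(trace: SignalTrace, n_average: int) -> SignalTrace:
    """Moving-window boxcar average of a trace.

    Output value ``k`` is the mean of the last ``min(k, n_average)``
    input samples; times are unchanged. The window ramps up at the start
    of the trace, so no samples are dropped.
    """
    if n_average < 1:
        raise ConfigurationError("n_average must be >= 1")
    if len(trace) == 0:
        return SignalTrace(np.empty(0), np.empty(0))
    filtered = (
        pd.Series(trace.values).rolling(n_average, min_periods=1).mean().to_numpy()
    )
    return SignalTrace(trace.times.copy(), filtered)


class BoxcarStream:
    """Streaming counterpart of :func:`boxcar_filter` for the event loop."""

    def __init__(self, n_average: int) -> None:
        if n_average < 1:
            raise ConfigurationError("n_average must be >= 1")
        self._window: deque[float] = deque(maxlen=n_average)

    def update(self, value: float) -> float:
        self._window.append(float(value))
        return sum(self._window) / len(self._window)

    def replace_last(self, value: float) -> float:
        """Overwrite the most recent sample (used when a provisional
        grid sample is superseded by an exact threshold crossing)."""
        if not self._window:
            raise StateError("no sample to replace")
        self._window.pop()
        return self.update(value)


def sample_measurement(
    true_T: float,
    acq: AcquisitionSettings,
    calib: CalibrationRecord,
    rng: np.random.Generator,
) -> float:
    """Simulate one raw detector reading for a true transmittance.

    The true transmittance is mapped onto the calibrated raw scale and
    Gaussian noise of ``acq.noise_sd`` raw units is added — noise lives
    in raw-signal space, where a real photoreceiver's noise lives. With
    ``noise_sd == 0`` the reading round-trips exactly through
    :func:`raw_to_transmittance`.
    """
    raw = calib.dark_signal + calib.span * true_T / 100.0
    if acq.noise_sd > 0:
        raw += rng.normal(0.0, acq.noise_sd)
    return float(raw)
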