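"""Closed-loop controller: the four operating modes as an event loop.

The engine drives one channel of any driver implementing the hardware
contract (:mod:`microstat.rig`). Every sample period it reads the
detector, calibrates, boxcar-filters, and evaluates the configured mode:

* **BatchMonitor** — measure only, never refresh;
* **RealTimeFeedback** — turbidostat: start refreshing when the
  filtered transmittance crosses ``trigger_T`` in the growth direction,
  keep diluting (in cycles capped at ``max_cycle_pinch_time``,
  re-measuring after each) until it crosses back past ``release_T``;
* **ThresholdActivated** — turbidostat variant: on the trigger
  crossing run exactly ``n_cycles`` cycles of ``pinch_time`` each,
  then re-arm immediately;
* **TimeInterval** — chemostat: once armed (at a clock time or a
  transmittance value), refresh every ``period`` seconds, each refresh
  ended by a total pinch time or a transmittance threshold.

Threshold comparisons are inclusive, so in noise-free runs the trigger
value itself is the extremum of the filtered signal. Signal polarity is
explicit: turbidity readouts fall with growth, phenol-red readouts
rise, and the trigger/release thresholds must sit on the correct sides
for the configured polarity.

Simulation-only *event-exact* mode removes grid quantization: threshold
crossings are located by root finding on the virtual culture (the rig
must support snapshot/look-ahead) and the final dilution cycle is
trimmed so dilution halts exactly at the stop threshold. It requires
noise to be off and makes control decisions on the instantaneous
calibrated transmittance, since the boxcar's group delay is precisely
the sampling artifact the mode exists to remove.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import warnings
from dataclasses import dataclass
from typing import Union

from scipy.optimize import brentq

from ._version import __version__
from .culture import MediumSpec, OrganismParams
from .errors import (
    ConfigurationError,
    DomainError,
    FluidicsError,
    IntegrationError,
)
from .fluidics import (
    FlowCalibration,
    VesselSpec,
    max_pinch_time,
    pinch_time_for_volume,
    volume_delivered,
)
from .logio import ExperimentLog
from .optics import AcquisitionSettings, BoxcarStream, CalibrationRecord, raw_to_transmittance
from .rig import VALVE_NORMAL, VALVE_REFRESH

__all__ = [
    "Polarity",
    "BatchMonitor",
    "RealTimeFeedback",
    "ThresholdActivated",
    "TimeInterval",
    "AtTime",
    "AtTransmittance",
    "AfterPinchTime",
    "AtThreshold",
    "ModeConfig",
    "ExperimentConfig",
    "Decision",
    "ControllerPhase",
    "trigger_check",
    "plan_refresh_cycles",
    "effective_dilution_rate",
    "run_experiment",
    "validate_mode",
]


class Polarity(enum.Enum):
    """Which way the optical signal moves as the culture grows."""

    GROWTH_DECREASES_T = "growth_decreases_T"  # turbidity readout
    GROWTH_INCREASES_T = "growth_increases_T"  # phenol-red readout

    @property
    def growth_direction(self) -> int:
        """+1 if growth raises transmittance, -1 if it lowers it."""
        return 1 if self is Polarity.GROWTH_INCREASES_T else -1


# -- mode configurations ----------------------------------------------------


@dataclass(frozen=True)
class BatchMonitor:
    """Measure only; the valve never opens."""


@dataclass(frozen=True)
class RealTimeFeedback:
    """Turbidostat: dilute from ``trigger_T`` back to ``release_T``."""

    trigger_T: float
    release_T: float
    max_cycle_pinch_time: float


@dataclass(frozen=True)
class ThresholdActivated:
    """On trigger, run a fixed number of fixed-length cycles, then re-arm."""

    trigger_T: float
    pinch_time: float
    n_cycles: int = 1


@dataclass(frozen=True)
class AtTime:
    """Start condition: arm the interval timer at a clock time (s)."""

    t: float


@dataclass(frozen=True)
class AtTransmittance:
    """Start condition: arm when the signal crosses a value (growth direction)."""

    percent: float


@dataclass(frozen=True)
class AfterPinchTime:
    """Stop condition: each refresh delivers a fixed total pinch time (s)."""

    pinch_time: float


@dataclass(frozen=True)
class AtThreshold:
    """Stop condition: each refresh dilutes until the signal crosses back."""

    percent: float


@dataclass(frozen=True)
class TimeInterval:
    """Chemostat: refresh every ``period`` seconds once armed."""

    period: float
    start_condition: Union[AtTime, AtTransmittance]
    stop_condition: Union[AfterPinchTime, AtThreshold]


ModeConfig = Union[BatchMonitor, RealTimeFeedback, ThresholdActivated, TimeInterval]


def validate_mode(
    mode: ModeConfig,
    polarity: Polarity,
    vessel: VesselSpec,
    flow: FlowCalibration,
) -> None:
    """Check mode invariants; raise :class:`ConfigurationError` naming the fault."""
    cap = max_pinch_time(vessel, flow)
    if isinstance(mode, RealTimeFeedback):
        d = polarity.growth_direction
        if not d * (mode.trigger_T - mode.release_T) > 0:
            raise ConfigurationError(
                "trigger_T/release_T must sit on opposite sides of the band for "
                f"polarity {polarity.value}: trigger={mode.trigger_T}, "
                f"release={mode.release_T}"
            )
        if not 0 < mode.max_cycle_pinch_time <= cap:
            raise ConfigurationError(
                f"max_cycle_pinch_time={mode.max_cycle_pinch_time} s exceeds the "
                f"overflow-safe maximum {cap} s"
            )
    elif isinstance(mode, ThresholdActivated):
        if not 0 < mode.pinch_time <= cap:
            raise ConfigurationError(
                f"pinch_time={mode.pinch_time} s exceeds the overflow-safe maximum {cap} s"
            )
        if mode.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
    elif isinstance(mode, TimeInterval):
        if not mode.period > 0:
            raise ConfigurationError("period must be > 0")
        if isinstance(mode.stop_condition, AfterPinchTime):
            if mode.stop_condition.pinch_time < 0:
                raise ConfigurationError("stop pinch_time must be >= 0")
    elif not isinstance(mode, BatchMonitor):
        raise ConfigurationError(f"unknown mode {mode!r}")


# -- control decisions -------------------------------------------------------


class Decision(enum.Enum):
    IDLE = "idle"
    START_REFRESH = "start_refresh"
    CONTINUE_REFRESH = "continue_refresh"
    STOP_REFRESH = "stop_refresh"


@dataclass
class ControllerPhase:
    """Mutable per-channel controller state between samples."""

    state: str = "idle"  # "idle" | "refreshing"
    armed: bool = False  # TimeInterval only
    next_refresh_t: float | None = None


def _crossed(value: float, threshold: float, direction: int) -> bool:
    """Inclusive crossing test in the given direction (+1 up, -1 down)."""
    return direction * (value - threshold) >= 0


def trigger_check(
    filtered_T: float,
    t_s: float,
    mode: ModeConfig,
    polarity: Polarity,
    phase: ControllerPhase,
) -> Decision:
    """Pure control decision for one sample.

    ``filtered_T`` is the value the mode acts on (boxcar output, or the
    instantaneous reading in event-exact simulation); ``t_s`` the clock.
    The function never mutates ``phase``.
    """
    if not math.isfinite(filtered_T):
        raise DomainError(f"non-finite transmittance {filtered_T}")
    d = polarity.growth_direction
    if isinstance(mode, BatchMonitor):
        return Decision.IDLE
    if isinstance(mode, RealTimeFeedback):
        if phase.state == "refreshing":
            if _crossed(filtered_T, mode.release_T, -d):
                return Decision.STOP_REFRESH
            return Decision.CONTINUE_REFRESH
        return (
            Decision.START_REFRESH
            if _crossed(filtered_T, mode.trigger_T, d)
            else Decision.IDLE
        )
    if isinstance(mode, ThresholdActivated):
        if phase.state == "refreshing":
            return Decision.CONTINUE_REFRESH  # cycle count is managed by the loop
        return (
            Decision.START_REFRESH
            if _crossed(filtered_T, mode.trigger_T, d)
            else Decision.IDLE
        )
    if isinstance(mode, TimeInterval):
        if phase.state == "refreshing":
            stop = mode.stop_condition
            if isinstance(stop, AtThreshold) and _crossed(filtered_T, stop.percent, -d):
                return Decision.STOP_REFRESH
            return Decision.CONTINUE_REFRESH
        if not phase.armed:
            start = mode.start_condition
            met = (
                t_s >= start.t
                if isinstance(start, AtTime)
                else _crossed(filtered_T, start.percent, d)
            )
            return Decision.START_REFRESH if met else Decision.IDLE
        if phase.next_refresh_t is not None and t_s >= phase.next_refresh_t - 1e-9:
            return Decision.START_REFRESH
        return Decision.IDLE
    raise ConfigurationError(f"unknown mode {mode!r}")


def effective_dilution_rate(period_s: float, delivered_mL: float, working_mL: float) -> float:
    """Exact per-pulse dilution rate, per hour.

    One pulse multiplies concentrations by ``w / (w + v)``; repeating
    every ``period`` gives ``D = ln((w + v)/w) / period``. For small
    pulses this reduces to the familiar ``v / (w * period)``.
    """
    if not period_s > 0:
        raise DomainError("period must be > 0")
    if delivered_mL < 0:
        raise DomainError("delivered volume must be >= 0")
    return math.log((working_mL + delivered_mL) / working_mL) / period_s * 3600.0


def plan_refresh_cycles(
    stop_condition,
    max_cycle_pinch_time: float,
    measure=None,
    direction: int | None = None,
    cycle_cap: int = 100,
):
    """Yield pinch times (s) for one refresh until the stop condition holds.

    For :class:`AfterPinchTime` the total pinch time is chunked into
    cycles of at most ``max_cycle_pinch_time``. For :class:`AtThreshold`
    the ``measure`` callback is invoked between cycles (re-measured
    signal) and cycles of ``max_cycle_pinch_time`` are emitted until the
    threshold is crossed against the growth ``direction``; after
    ``cycle_cap`` cycles a warning is raised and the refresh ends — the
    stop value may simply be unreachable (e.g. below the fresh-medium
    transmittance).
    """
    if isinstance(stop_condition, AfterPinchTime):
        remaining = stop_condition.pinch_time
        while remaining > 1e-12:
            chunk = min(remaining, max_cycle_pinch_time)
            remaining -= chunk
            yield chunk
        return
    if isinstance(stop_condition, AtThreshold):
        if measure is None or direction is None:
            raise ConfigurationError("AtThreshold stop needs a measure callback and direction")
        n = 0
        while not _crossed(measure(), stop_condition.percent, -direction):
            if n >= cycle_cap:
                warnings.warn(
                    f"refresh stopped after {cycle_cap} cycles without reaching "
                    f"{stop_condition.percent}% — stop value may be unreachable",
                    stacklevel=2,
                )
                return
            yield max_cycle_pinch_time
            n += 1
        return
    raise ConfigurationError(f"unknown stop condition {stop_condition!r}")


# -- experiment configuration and the event loop ------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one channel needs for a closed-loop run."""

    duration_h: float
    acquisition: AcquisitionSettings
    mode: ModeConfig
    polarity: Polarity
    organism: OrganismParams
    medium: MediumSpec
    vessel: VesselSpec = VesselSpec()
    flow: FlowCalibration = FlowCalibration()
    calibration: CalibrationRecord = CalibrationRecord(0.0, 10.0)
    channel_id: int = 1

    def __post_init__(self) -> None:
        if not self.duration_h > 0:
            raise ConfigurationError("duration_h must be > 0")
        if self.channel_id not in (1, 2, 3):
            raise ConfigurationError("channel_id must be 1, 2 or 3")
        validate_mode(self.mode, self.polarity, self.vessel, self.flow)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {"kind": type(obj).__name__}
        for f in dataclasses.fields(obj):
            out[f.name] = _jsonable(getattr(obj, f.name))
        return out
    if isinstance(obj, enum.Enum):
        return obj.value
    return obj


_NAN = float("nan")


def run_experiment(
    hardware,
    config: ExperimentConfig,
    *,
    event_exact: bool = False,
    cycle_cap: int = 100,
) -> ExperimentLog:
    """Run one channel closed-loop and return its log.

    ``event_exact`` (simulation only) removes sampling-grid quantization
    from threshold detection; it requires a rig exposing snapshot /
    look-ahead methods and ``noise_sd == 0``. Overflow or hardware
    faults abort the run; the partial log is returned with
    ``metadata["aborted"]`` set.
    """
    acq = config.acquisition
    mode, polarity = config.mode, config.polarity
    ch = config.channel_id
    calib = config.calibration
    d = polarity.growth_direction
    validate_mode(mode, polarity, config.vessel, config.flow)
    if event_exact:
        needed = ("snapshot", "restore", "evolve", "true_transmittance", "transmittance_after_mix")
        if not all(hasattr(hardware, m) for m in needed):
            raise ConfigurationError("event-exact mode needs a rig with snapshot/look-ahead support")
        if acq.noise_sd != 0:
            raise ConfigurationError("event-exact mode requires noise_sd == 0")

    filt = BoxcarStream(acq.n_average)
    phase = ControllerPhase()
    records: list[dict] = []
    cum_medium = 0.0
    duration_s = config.duration_h * 3600.0
    single_cycle_cap = max_pinch_time(config.vessel, config.flow)

    def _sample(phase_label: str) -> tuple[float, float]:
        raw = hardware.read_signal(ch)
        T = raw_to_transmittance(raw, calib).percent
        fT = filt.update(T)
        records.append(
            {
                "time_s": hardware.clock,
                "channel": ch,
                "raw": raw,
                "transmittance_pct": T,
                "filtered_pct": fT,
                "phase": phase_label,
                "event": "",
                "pinch_time_s": _NAN,
                "volume_added_mL": _NAN,
                "volume_removed_mL": _NAN,
                "cumulative_medium_mL": _NAN,
            }
        )
        return T, fT

    def _event(name: str, T=_NAN, fT=_NAN, pinch=_NAN, added=_NAN, removed=_NAN) -> None:
        records.append(
            {
                "time_s": hardware.clock,
                "channel": ch,
                "raw": _NAN,
                "transmittance_pct": T,
                "filtered_pct": fT,
                "phase": phase.state,
                "event": name,
                "pinch_time_s": pinch,
                "volume_added_mL": added,
                "volume_removed_mL": removed,
                "cumulative_medium_mL": cum_medium,
            }
        )

    def _do_cycle(pinch: float) -> None:
        nonlocal cum_medium
        delivered = volume_delivered(pinch, config.flow)
        if config.vessel.working_volume + delivered > config.vessel.capacity + 1e-12:
            raise FluidicsError(
                f"cycle of {pinch} s would overflow the {config.vessel.capacity} mL vessel"
            )
        t0 = hardware.clock
        hardware.set_valve(ch, VALVE_REFRESH)
        hardware.sleep(pinch)
        hardware.set_valve(ch, VALVE_NORMAL)
        cum_medium += delivered
        records.append(
            {
                "time_s": t0,
                "channel": ch,
                "raw": _NAN,
                "transmittance_pct": _NAN,
                "filtered_pct": _NAN,
                "phase": "refreshing",
                "event": "refresh_cycle",
                "pinch_time_s": pinch,
                "volume_added_mL": delivered,
                "volume_removed_mL": delivered,
                "cumulative_medium_mL": cum_medium,
            }
        )

    def _settle_and_sample() -> tuple[float, float]:
        hardware.sleep(acq.sample_period)
        return _sample("refreshing")

    def _refine_trigger(prev_state, prev_clock: float, trigger_T: float):
        """Locate the exact trigger crossing inside the last sample interval."""
        dt_full = hardware.clock - prev_clock
        if dt_full <= 0:
            return None

        def g(s: float) -> float:
            return d * (hardware.true_transmittance(hardware.evolve(prev_state, s)) - trigger_T)

        if g(0.0) >= 0 or g(dt_full) < 0:
            return None  # crossing not bracketed; keep the grid sample
        s_star = brentq(g, 0.0, dt_full, xtol=1e-10)
        hardware.restore(hardware.evolve(prev_state, s_star), clock=prev_clock + s_star)
        records.pop()  # provisional grid sample, superseded by the crossing
        T = hardware.true_transmittance()
        raw = calib.dark_signal + calib.span * T / 100.0
        fT = filt.replace_last(T)
        records.append(
            {
                "time_s": hardware.clock,
                "channel": ch,
                "raw": raw,
                "transmittance_pct": T,
                "filtered_pct": fT,
                "phase": "idle",
                "event": "",
                "pinch_time_s": _NAN,
                "volume_added_mL": _NAN,
                "volume_removed_mL": _NAN,
                "cumulative_medium_mL": _NAN,
            }
        )
        return T, fT

    def _refresh_to_threshold(stop_T: float, max_cycle: float, T: float, fT: float) -> None:
        """Grid-mode dilution: full cycles with a settle sample between."""
        n = 0
        decision_T = T if event_exact else fT
        while trigger_check(decision_T, hardware.clock, mode, polarity, phase) is not Decision.STOP_REFRESH:
            if n >= cycle_cap:
                warnings.warn(
                    f"refresh stopped after {cycle_cap} cycles without reaching "
                    f"{stop_T}% — stop value may be unreachable",
                    stacklevel=2,
                )
                break
            _do_cycle(max_cycle)
            T, fT = _settle_and_sample()
            decision_T = T if event_exact else fT
            n += 1
        _event("refresh_stop", T=T, fT=fT)

    def _refresh_to_threshold_exact(stop_T: float, max_cycle: float) -> None:
        """Event-exact dilution: the final cycle is trimmed by root finding."""
        n = 0
        while True:
            T = hardware.true_transmittance()
            # tolerance absorbs the root-finder's residual on the trimmed cycle
            if d * (T - stop_T) <= 1e-9:
                break
            if n >= cycle_cap:
                warnings.warn(
                    f"refresh stopped after {cycle_cap} cycles without reaching "
                    f"{stop_T}% — stop value may be unreachable",
                    stacklevel=2,
                )
                break
            dv_max = volume_delivered(max_cycle, config.flow)

            def f(dv: float) -> float:
                return d * (hardware.transmittance_after_mix(dv) - stop_T)

            if f(dv_max) > 0:
                _do_cycle(max_cycle)  # a full cycle still leaves us short
            else:
                dv_star = brentq(f, 0.0, dv_max, xtol=1e-12)
                _do_cycle(pinch_time_for_volume(dv_star, config.flow))
            n += 1
        T = hardware.true_transmittance()
        _event("refresh_stop", T=T, fT=T)

    def _execute_refresh(T: float, fT: float) -> None:
        phase.state = "refreshing"
        _event("refresh_start", T=T, fT=fT)
        if isinstance(mode, RealTimeFeedback):
            if event_exact:
                _refresh_to_threshold_exact(mode.release_T, mode.max_cycle_pinch_time)
            else:
                _refresh_to_threshold(mode.release_T, mode.max_cycle_pinch_time, T, fT)
        elif isinstance(mode, ThresholdActivated):
            for i in range(mode.n_cycles):
                _do_cycle(mode.pinch_time)
                if i < mode.n_cycles - 1:
                    _settle_and_sample()
            _event("refresh_stop")
        elif isinstance(mode, TimeInterval):
            stop = mode.stop_condition
            if isinstance(stop, AfterPinchTime):
                first = True
                for pinch in plan_refresh_cycles(stop, single_cycle_cap):
                    if not first:
                        _settle_and_sample()
                    _do_cycle(pinch)
                    first = False
                _event("refresh_stop")
            elif event_exact:
                _refresh_to_threshold_exact(stop.percent, single_cycle_cap)
            else:
                _refresh_to_threshold(stop.percent, single_cycle_cap, T, fT)
        phase.state = "idle"

    aborted: str | None = None
    prev_state = None
    prev_clock = 0.0
    try:
        while hardware.clock <= duration_s + 1e-9:
            T, fT = _sample(phase.state)
            decision_T = T if event_exact else fT
            decision = trigger_check(decision_T, hardware.clock, mode, polarity, phase)
            if decision is Decision.START_REFRESH:
                if (
                    event_exact
                    and prev_state is not None
                    and isinstance(mode, (RealTimeFeedback, ThresholdActivated))
                ):
                    refined = _refine_trigger(prev_state, prev_clock, mode.trigger_T)
                    if refined is not None:
                        T, fT = refined
                if isinstance(mode, TimeInterval):
                    if not phase.armed:
                        phase.armed = True
                        phase.next_refresh_t = hardware.clock
                    _execute_refresh(T, fT)
                    phase.next_refresh_t = max(
                        phase.next_refresh_t + mode.period, hardware.clock
                    )
                else:
                    _execute_refresh(T, fT)
            prev_state = hardware.snapshot() if event_exact else None
            prev_clock = hardware.clock
            hardware.sleep(acq.sample_period)
    except (FluidicsError, IntegrationError) as exc:
        aborted = f"{type(exc).__name__}: {exc}"
        phase.state = "aborted"
        _event("abort")
        warnings.warn(f"experiment aborted: {aborted}", stacklevel=2)

    metadata = {
        "config": _jsonable(config),
        "event_exact": event_exact,
        "seed": getattr(hardware, "seed", None),
        "software_version": __version__,
    }
    if aborted:
        metadata["aborted"] = aborted
    return ExperimentLog.from_records(records, metadata)
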