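"""Pinch-valve refresh mechanics.

A refresh cycle has two steps: (A) the four-way valve diverts air
pressure to the medium bottle, pushing fresh medium into the vessel for
the programmed *pinch time*; (B) the valve returns to rest and the
excess volume above the working volume is evacuated to the trash
bottle. Delivered volume is linear in pinch time above a dead time
(tubing lag), per flow calibration.

Delivery is modeled as instantaneous at cycle end: pinch times (tens of
seconds at most) are far below doubling times (tens of minutes or
more), so growth during a cycle is negligible and the model stays
event-driven.
"""

from __future__ import annotations

from dataclasses import dataclass

from .culture import CultureState, MediumSpec, draw_off, mix_in
from .errors import ConfigurationError, DomainError, FluidicsError, OverflowGuardError

__all__ = [
    "VesselSpec",
    "FlowCalibration",
    "RefreshCycleRecord",
    "volume_delivered",
    "pinch_time_for_volume",
    "max_pinch_time",
    "execute_refresh_cycle",
]


@dataclass(frozen=True)
class VesselSpec:
    """Culture vessel geometry: 55 mL tube, 20 mL working volume by default."""

    capacity: float = 55.0
    working_volume: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.working_volume < self.capacity:
            raise ConfigurationError("require 0 < working_volume < capacity")

    @property
    def headroom(self) -> float:
        """Largest volume a single cycle may add without overflow (mL)."""
        return self.capacity - self.working_volume


@dataclass(frozen=True)
class FlowCalibration:
    """Calibrated delivery: ``rate`` mL/s above a ``dead_time`` lag (s)."""

    rate: float = 1.0
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ConfigurationError("flow rate must be > 0")
        if self.dead_time < 0:
            raise ConfigurationError("dead_time must be >= 0")


@dataclass(frozen=True)
class RefreshCycleRecord:
    """Bookkeeping for one completed refresh cycle (times in seconds)."""

    t_start: float
    pinch_time: float
    volume_added: float
    volume_removed: float


def volume_delivered(pinch_time: float, calib: FlowCalibration) -> float:
    """Volume (mL) delivered by holding the valve open for ``pinch_time`` s."""
    if pinch_time < 0:
        raise DomainError("pinch_time must be >= 0")
    return calib.rate * max(0.0, pinch_time - calib.dead_time)


def pinch_time_for_volume(dV: float, calib: FlowCalibration) -> float:
    """Pinch time (s) needed to deliver ``dV`` mL (inverse of delivery)."""
    if dV < 0:
        raise DomainError("dV must be >= 0")
    if dV == 0:
        return 0.0
    return dV / calib.rate + calib.dead_time


def max_pinch_time(vessel: VesselSpec, calib: FlowCalibration) -> float:
    """Largest single-cycle pinch time that cannot overflow the vessel."""
    return vessel.headroom / calib.rate + calib.dead_time


def execute_refresh_cycle(
    state: CultureState,
    pinch_time: float,
    medium: MediumSpec,
    vessel: VesselSpec,
    calib: FlowCalibration,
) -> tuple[CultureState, RefreshCycleRecord]:
    """Run one complete refresh cycle: dilute, then restore working volume.

    Preconditions: the vessel is at working volume. The overflow guard
    fires *before* any state change. After the cycle the volume equals
    the working volume again and added == removed.
    """
    if abs(state.V - vessel.working_volume) > 1e-9:
        raise FluidicsError(
            f"cycle must start at working volume {vessel.working_volume} mL "
            f"(vessel at {state.V} mL)"
        )
    delivered = volume_delivered(pinch_time, calib)
    if vessel.working_volume + delivered > vessel.capacity + 1e-12:
        raise OverflowGuardError(
            f"delivering {delivered:.3f} mL onto {vessel.working_volume} mL "
            f"would exceed the {vessel.capacity} mL capacity"
        )
    record = RefreshCycleRecord(
        t_start=state.t * 3600.0,
        pinch_time=pinch_time,
        volume_added=delivered,
        volume_removed=delivered,
    )
    if delivered == 0:
        return state, record
    new_state = draw_off(mix_in(state, delivered, medium), vessel.working_volume)
    return new_state, record
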