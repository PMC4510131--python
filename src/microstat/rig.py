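"""Hardware contract and the simulated rig.

The controller talks to hardware through a minimal synchronous
contract; any driver implementing it can be used:

* ``read_signal(channel) -> raw`` — one detector reading, returns promptly;
* ``set_valve(channel, position)`` — ``"normal"`` or ``"refresh"``;
* ``set_mixer(channel, on)`` — stir bar on/off;
* ``sleep(seconds)`` / ``clock`` — pacing. A real driver sleeps in wall
  time; the simulated rig advances a virtual clock instead, so
  simulations run as fast as the CPU allows.

:class:`SimulatedRig` implements the contract by composing the culture,
fluidics and optics models: while the valve is in its normal position,
``sleep`` integrates growth; while it is in the refresh position, the
open time accumulates and, on valve return, the corresponding medium
volume is mixed in and the excess drawn off (instantaneous-delivery
model). The rig additionally supports state snapshot/restore and pure
look-ahead queries, which the controller's event-exact mode uses to
locate threshold crossings by root finding — something a physical rig
cannot do.
"""

from __future__ import annotations

import math
from typing import Protocol, runtime_checkable

import numpy as np

from . import culture, fluidics, optics
from .culture import CultureState, MediumSpec, OrganismParams
from .errors import FluidicsError
from .fluidics import FlowCalibration, VesselSpec
from .optics import AcquisitionSettings, CalibrationRecord

__all__ = ["Hardware", "SimulatedRig", "model_transmittance"]

VALVE_NORMAL = "normal"
VALVE_REFRESH = "refresh"


@runtime_checkable
class Hardware(Protocol):
    """The synchronous driver contract the controller runs against."""

    clock: float

    def read_signal(self, channel: int) -> float: ...

    def set_valve(self, channel: int, position: str) -> None: ...

    def set_mixer(self, channel: int, on: bool) -> None: ...

    def sleep(self, seconds: float) -> None: ...


def model_transmittance(
    state: CultureState, org: OrganismParams, medium: MediumSpec
) -> float:
    """True percent transmittance of a culture state (no detector noise).

    Absorbance contributions add: turbidity (linear in cell density)
    plus, for phenol-red medium, the pH-dependent indicator term.
    """
    A_cells = optics.cell_absorbance(state.X, org.optics)
    A_medium = 0.0
    if medium.phenol_red:
        A_medium = optics.phenolred_absorbance(culture.culture_pH(state, medium), org.optics)
    return optics.transmittance_from_components(A_cells, A_medium)


class SimulatedRig:
    """Virtual single-channel rig: culture + fluidics + optics.

    Parameters mirror a physical channel. ``seed`` feeds the detector
    noise generator (irrelevant when ``acquisition.noise_sd == 0`` but
    always recorded for reproducibility).
    """

    def __init__(
        self,
        organism: OrganismParams,
        medium: MediumSpec,
        vessel: VesselSpec,
        flow: FlowCalibration,
        calibration: CalibrationRecord,
        acquisition: AcquisitionSettings,
        initial_state: CultureState,
        seed: int = 0,
        channel: int = 1,
    ) -> None:
        self.organism = organism
        self.medium = medium
        self.vessel = vessel
        self.flow = flow
        self.calibration = calibration
        self.acquisition = acquisition
        self.state = initial_state
        self.seed = int(seed)
        self.channel = channel
        self.rng = np.random.default_rng(self.seed)
        self.clock = 0.0
        self.mixer_on = True
        self.growth_integral = 0.0  # cumulative ∫ mu dt, natural-log units
        self._valve = VALVE_NORMAL
        self._valve_open_since: float | None = None
        self.last_cycle: fluidics.RefreshCycleRecord | None = None

    # -- hardware contract -------------------------------------------------

    def read_signal(self, channel: int) -> float:
        self._check_channel(channel)
        return optics.sample_measurement(
            self.true_transmittance(), self.acquisition, self.calibration, self.rng
        )

    def set_valve(self, channel: int, position: str) -> None:
        self._check_channel(channel)
        if position not in (VALVE_NORMAL, VALVE_REFRESH):
            raise FluidicsError(f"unknown valve position {position!r}")
        if position == self._valve:
            return
        if position == VALVE_REFRESH:
            self._valve_open_since = self.clock
        else:
            opened = self._valve_open_since if self._valve_open_since is not None else self.clock
            pinch = self.clock - opened
            self._valve_open_since = None
            self.state, self.last_cycle = fluidics.execute_refresh_cycle(
                self.state, pinch, self.medium, self.vessel, self.flow
            )
        self._valve = position

    def set_mixer(self, channel: int, on: bool) -> None:
        self._check_channel(channel)
        self.mixer_on = bool(on)

    def sleep(self, seconds: float) -> None:
        # Growth advances only while the valve is at rest; the seconds a
        # cycle keeps the valve open are counted on the clock but treated
        # as growth-free (instantaneous-delivery model).
        if seconds < 0:
            raise FluidicsError("cannot sleep a negative duration")
        if seconds == 0:
            return
        if self._valve == VALVE_NORMAL and self.state.X >= 0:
            old_X = self.state.X
            self.state = culture.advance(
                self.state, seconds / 3600.0, self.organism, self.medium
            )
            if old_X > 0 and self.state.X > 0:
                self.growth_integral += math.log(self.state.X / old_X)
        self.clock += seconds

    # -- simulation-only capabilities --------------------------------------

    def true_transmittance(self, state: CultureState | None = None) -> float:
        """Noise-free transmittance of ``state`` (default: current state)."""
        return model_transmittance(state or self.state, self.organism, self.medium)

    def snapshot(self) -> CultureState:
        return self.state  # CultureState is frozen; sharing is safe

    def restore(self, state: CultureState, clock: float | None = None) -> None:
        self.state = state
        if clock is not None:
            self.clock = clock

    def evolve(self, state: CultureState, seconds: float) -> CultureState:
        """Pure look-ahead: ``state`` after ``seconds`` of undisturbed growth."""
        if seconds <= 0:
            return state
        return culture.advance(state, seconds / 3600.0, self.organism, self.medium)

    def transmittance_after_mix(self, dV: float) -> float:
        """Pure look-ahead: transmittance after mixing in ``dV`` mL.

        Drawing off does not change concentrations, so this equals the
        post-cycle transmittance for a delivery of ``dV``.
        """
        return self.true_transmittance(culture.mix_in(self.state, dV, self.medium))

    def _check_channel(self, channel: int) -> None:
        if channel != self.channel:
            raise FluidicsError(
                f"rig drives channel {self.channel}, not channel {channel}"
            )
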