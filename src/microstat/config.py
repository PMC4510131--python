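"""Run-configuration schema: validated, versioned, YAML-serialized.

A run config describes up to three independent channels. Each channel
bundles the organism and medium parameters, the optical calibration,
vessel and flow calibration, acquisition settings, the operating mode,
and the initial culture state. The schema is strict (unknown keys are
rejected) and cross-field invariants — threshold ordering versus signal
polarity, pinch times versus the overflow-safe maximum — are enforced
at load time so a bad config fails before any experiment starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Annotated, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import controller, culture, fluidics, optics
from .controller import ExperimentConfig, Polarity
from .errors import ConfigurationError

__all__ = [
    "RunConfig",
    "ChannelModel",
    "load_config",
    "save_config",
    "to_experiment_config",
    "to_initial_state",
]

SCHEMA_VERSION = 1


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsModel(_Base):
    k_cell: float = Field(0.0, ge=0)
    path_length: float = Field(1.0, gt=0)
    phenolred_A_min: float = Field(0.0, ge=0)
    phenolred_A_max: float = Field(0.0, ge=0)
    pH_lo: float = 6.0
    pH_hi: float = 7.0

    @model_validator(mode="after")
    def _check(self):
        if self.phenolred_A_max < self.phenolred_A_min:
            raise ValueError("phenolred_A_max must be >= phenolred_A_min")
        if not self.pH_hi > self.pH_lo:
            raise ValueError("pH_hi must be > pH_lo")
        return self


class OrganismModel(_Base):
    mu_max: float = Field(gt=0, description="maximum specific growth rate, per hour")
    Ks: float = Field(gt=0, description="Monod half-saturation constant, g/L")
    yield_Y: float = Field(gt=0, description="cells produced per gram of substrate")
    q_acid: float = Field(0.0, ge=0, description="acid units produced per cell grown")
    optics: OpticsModel = OpticsModel()


class MediumModel(_Base):
    S0: float = Field(ge=0, description="limiting substrate in fresh medium, g/L")
    pH0: float = 7.0
    buffer_capacity: float = Field(1.0, gt=0)
    phenol_red: bool = False


class CalibrationModel(_Base):
    dark_signal: float
    blank_signal: float
    wavelength: float = optics.WAVELENGTH_NM
    label: str = ""

    @model_validator(mode="after")
    def _check(self):
        if self.blank_signal <= self.dark_signal:
            raise ValueError("blank_signal must be > dark_signal")
        return self


class VesselModel(_Base):
    capacity: float = 55.0
    working_volume: float = 20.0

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.working_volume < self.capacity:
            raise ValueError("require 0 < working_volume < capacity")
        return self


class FlowModel(_Base):
    rate: float = Field(1.0, gt=0, description="mL delivered per second of pinch time")
    dead_time: float = Field(0.0, ge=0)


class AcquisitionModel(_Base):
    sample_period: float = Field(5.0, gt=0)
    n_average: int = Field(1, ge=1)
    noise_sd: float = Field(0.0, ge=0)


class InitialStateModel(_Base):
    X0: float = Field(ge=0, description="initial cell density, CFU/mL")
    V: Optional[float] = Field(None, description="initial volume, default working volume")
    S: Optional[float] = Field(None, description="initial substrate, default fresh-medium S0")
    C_acid: float = Field(0.0, ge=0)


class BatchModeModel(_Base):
    kind: Literal["batch"] = "batch"


class RealTimeFeedbackModel(_Base):
    kind: Literal["realtime-feedback"] = "realtime-feedback"
    trigger_T: float
    release_T: float
    max_cycle_pinch_time: float = Field(gt=0)


class ThresholdActivatedModel(_Base):
    kind: Literal["threshold-activated"] = "threshold-activated"
    trigger_T: float
    pinch_time: float = Field(gt=0)
    n_cycles: int = Field(1, ge=1)


class StartConditionModel(_Base):
    at_time: Optional[float] = None
    at_transmittance: Optional[float] = None

    @model_validator(mode="after")
    def _check(self):
        if (self.at_time is None) == (self.at_transmittance is None):
            raise ValueError("start condition needs exactly one of at_time / at_transmittance")
        return self


class StopConditionModel(_Base):
    after_pinch_time: Optional[float] = None
    at_threshold: Optional[float] = None

    @model_validator(mode="after")
    def _check(self):
        if (self.after_pinch_time is None) == (self.at_threshold is None):
            raise ValueError("stop condition needs exactly one of after_pinch_time / at_threshold")
        return self


class TimeIntervalModel(_Base):
    kind: Literal["time-interval"] = "time-interval"
    period: float = Field(gt=0)
    start: StartConditionModel
    stop: StopConditionModel


ModeModel = Annotated[
    Union[BatchModeModel, RealTimeFeedbackModel, ThresholdActivatedModel, TimeIntervalModel],
    Field(discriminator="kind"),
]


class ChannelModel(_Base):
    channel_id: int = Field(ge=1, le=3)
    duration_h: float = Field(12.0, gt=0)
    polarity: Literal["growth_decreases_T", "growth_increases_T"]
    mode: ModeModel
    organism: OrganismModel
    medium: MediumModel
    calibration: CalibrationModel
    vessel: VesselModel = VesselModel()
    flow: FlowModel = FlowModel()
    acquisition: AcquisitionModel = AcquisitionModel()
    initial: InitialStateModel

    @model_validator(mode="after")
    def _cross_field(self):
        # Re-use the controller's invariants so config-level and
        # runtime-level validation cannot drift apart.
        try:
            to_experiment_config(self)
        except ConfigurationError as exc:
            raise ValueError(str(exc)) from exc
        return self


class RunConfig(_Base):
    """Top-level run description: global seed plus 1-3 channel blocks."""

    schema_version: Literal[1] = SCHEMA_VERSION
    seed: int = 0
    output_dir: Optional[str] = None
    channels: list[ChannelModel] = Field(min_length=1, max_length=3)

    @model_validator(mode="after")
    def _unique_channels(self):
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError(f"channel ids must be unique (got {ids})")
        return self


# -- conversion to runtime dataclasses ---------------------------------------


def _mode_from_model(m) -> controller.ModeConfig:
    if isinstance(m, BatchModeModel):
        return controller.BatchMonitor()
    if isinstance(m, RealTimeFeedbackModel):
        return controller.RealTimeFeedback(m.trigger_T, m.release_T, m.max_cycle_pinch_time)
    if isinstance(m, ThresholdActivatedModel):
        return controller.ThresholdActivated(m.trigger_T, m.pinch_time, m.n_cycles)
    start = (
        controller.AtTime(m.start.at_time)
        if m.start.at_time is not None
        else controller.AtTransmittance(m.start.at_transmittance)
    )
    stop = (
        controller.AfterPinchTime(m.stop.after_pinch_time)
        if m.stop.after_pinch_time is not None
        else controller.AtThreshold(m.stop.at_threshold)
    )
    return controller.TimeInterval(m.period, start, stop)


def to_experiment_config(ch: ChannelModel) -> ExperimentConfig:
    """Build the runtime :class:`ExperimentConfig` for one channel."""
    o = ch.organism
    return ExperimentConfig(
        duration_h=ch.duration_h,
        acquisition=optics.AcquisitionSettings(
            sample_period=ch.acquisition.sample_period,
            n_average=ch.acquisition.n_average,
            noise_sd=ch.acquisition.noise_sd,
        ),
        mode=_mode_from_model(ch.mode),
        polarity=Polarity(ch.polarity),
        organism=culture.OrganismParams(
            mu_max=o.mu_max,
            Ks=o.Ks,
            yield_Y=o.yield_Y,
            q_acid=o.q_acid,
            optics=optics.OpticalModelParams(**o.optics.model_dump()),
        ),
        medium=culture.MediumSpec(**ch.medium.model_dump()),
        vessel=fluidics.VesselSpec(**ch.vessel.model_dump()),
        flow=fluidics.FlowCalibration(**ch.flow.model_dump()),
        calibration=optics.CalibrationRecord(**ch.calibration.model_dump()),
        channel_id=ch.channel_id,
    )


def to_initial_state(ch: ChannelModel) -> culture.CultureState:
    """Initial :class:`CultureState` for one channel (defaults filled)."""
    return culture.CultureState(
        t=0.0,
        V=ch.initial.V if ch.initial.V is not None else ch.vessel.working_volume,
        X=ch.initial.X0,
        S=ch.initial.S if ch.initial.S is not None else ch.medium.S0,
        C_acid=ch.initial.C_acid,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; errors name the offending field."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Serialize a run config to YAML (round-trips through load_config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
    return path
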