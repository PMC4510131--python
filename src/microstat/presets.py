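"""Named rig fixtures for the three reference scenarios.

Each preset is a full single-channel :class:`~microstat.config.RunConfig`
reproducing one of the monitored-organism scenarios:

* ``ecoli-like`` — turbidity readout, fast grower; threshold-activated
  refreshing (minimum transmittance 50 %, one 3 s cycle per trigger);
* ``mflorum-like`` — mollicute-style culture read through phenol red
  (cells too small to scatter light; growth acidifies the medium and
  raises transmittance); real-time feedback band 11.5–12 %;
* ``yeast-like`` — turbidity readout, slower grower; threshold-activated
  refreshing.

The kinetic parameters are fixture choices, not measured values: growth
rates are set so the fast scenarios double roughly every 29 min
(ecoli-like, ~25 doublings in 12 h) and every 36 min (mflorum-like, ~20
doublings in 12 h), with substrate kept saturating so triggered modes
run at maximal growth rate. The phenol-red absorbance endpoints place
fresh medium at 8 % transmittance and pH 6 at 16 %, the transmittance
span a mollicute batch culture traverses.
"""

from __future__ import annotations

import math

from .config import RunConfig
from .errors import ConfigurationError

__all__ = ["PRESET_NAMES", "preset"]

_VESSEL = {"capacity": 55.0, "working_volume": 20.0}
_FLOW = {"rate": 1.0, "dead_time": 0.0}

# Phenol-red endpoints: fresh medium (pH >= 7) reads 8 % T, fully
# acidified (pH <= 6) reads 16 % T; the span is exactly log10(2).
_PHENOLRED_A_MAX = -math.log10(0.08)
_PHENOLRED_A_MIN = -math.log10(0.16)


def _ecoli_like() -> dict:
    return {
        "channel_id": 1,
        "duration_h": 12.0,
        "polarity": "growth_decreases_T",
        "mode": {
            "kind": "threshold-activated",
            "trigger_T": 50.0,
            "pinch_time": 3.0,
            "n_cycles": 1,
        },
        "organism": {
            "mu_max": math.log(2.0) / 0.48,  # ~25 doublings over 12 h
            "Ks": 0.05,
            "yield_Y": 1e8,
            "q_acid": 0.0,
            "optics": {"k_cell": 2e-9, "path_length": 1.0},
        },
        "medium": {"S0": 10.0, "pH0": 7.0, "buffer_capacity": 1.0, "phenol_red": False},
        "calibration": {"dark_signal": 0.0, "blank_signal": 10.0, "label": "broth blank"},
        "vessel": dict(_VESSEL),
        "flow": dict(_FLOW),
        "acquisition": {"sample_period": 5.0, "n_average": 1, "noise_sd": 0.0},
        "initial": {"X0": 5e7},
    }


def _mflorum_like() -> dict:
    return {
        "channel_id": 1,
        "duration_h": 12.0,
        "polarity": "growth_increases_T",
        "mode": {
            "kind": "realtime-feedback",
            "trigger_T": 12.0,
            "release_T": 11.5,
            "max_cycle_pinch_time": 2.0,
        },
        "organism": {
            "mu_max": math.log(2.0) / 0.6,  # ~20 doublings over 12 h
            "Ks": 0.05,
            "yield_Y": 2e8,
            "q_acid": 1e-9,
            "optics": {
                "k_cell": 0.0,
                "path_length": 1.0,
                "phenolred_A_min": _PHENOLRED_A_MIN,
                "phenolred_A_max": _PHENOLRED_A_MAX,
                "pH_lo": 6.0,
                "pH_hi": 7.0,
            },
        },
        "medium": {"S0": 10.0, "pH0": 7.0, "buffer_capacity": 1.0, "phenol_red": True},
        "calibration": {"dark_signal": 0.0, "blank_signal": 10.0, "label": "water blank"},
        "vessel": dict(_VESSEL),
        "flow": dict(_FLOW),
        "acquisition": {"sample_period": 0.5, "n_average": 2, "noise_sd": 0.0},
        "initial": {"X0": 1e7},
    }


def _yeast_like() -> dict:
    return {
        "channel_id": 1,
        "duration_h": 12.0,
        "polarity": "growth_decreases_T",
        "mode": {
            "kind": "threshold-activated",
            "trigger_T": 50.0,
            "pinch_time": 3.0,
            "n_cycles": 1,
        },
        "organism": {
            "mu_max": math.log(2.0) / 1.5,
            "Ks": 0.05,
            "yield_Y": 1e8,
            "q_acid": 0.0,
            "optics": {"k_cell": 2e-9, "path_length": 1.0},
        },
        "medium": {"S0": 20.0, "pH0": 6.5, "buffer_capacity": 1.0, "phenol_red": False},
        "calibration": {"dark_signal": 0.0, "blank_signal": 10.0, "label": "medium blank"},
        "vessel": dict(_VESSEL),
        "flow": dict(_FLOW),
        "acquisition": {"sample_period": 5.0, "n_average": 1, "noise_sd": 0.0},
        "initial": {"X0": 5e7},
    }


_FACTORIES = {
    "ecoli-like": _ecoli_like,
    "mflorum-like": _mflorum_like,
    "yeast-like": _yeast_like,
}

PRESET_NAMES = tuple(sorted(_FACTORIES))


def preset(name: str, duration_h: float | None = None, seed: int = 0) -> RunConfig:
    """Build a validated single-channel run config for a named preset."""
    if name not in _FACTORIES:
        raise ConfigurationError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    channel = _FACTORIES[name]()
    if duration_h is not None:
        channel["duration_h"] = duration_h
    return RunConfig.model_validate(
        {"schema_version": 1, "seed": seed, "channels": [channel]}
    )
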