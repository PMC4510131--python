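"""Glue between configs, simulated rigs and the controller.

Channels are fully independent: each gets its own rig seeded by a
deterministic function of the global seed and the channel id, so a
multi-channel run produces exactly the logs of the corresponding
single-channel runs.
"""

from __future__ import annotations

from .config import ChannelModel, RunConfig, to_experiment_config, to_initial_state
from .controller import run_experiment
from .logio import ExperimentLog
from .presets import preset
from .rig import SimulatedRig

__all__ = ["channel_seed", "build_rig", "run_channel", "run_config", "run_preset"]


def channel_seed(global_seed: int, channel_id: int) -> int:
    """Per-channel noise seed derived from the global seed (stays < 2**31)."""
    return (int(global_seed) + 7919 * int(channel_id)) % (2**31 - 1)


def build_rig(channel: ChannelModel, global_seed: int = 0) -> SimulatedRig:
    cfg = to_experiment_config(channel)
    return SimulatedRig(
        organism=cfg.organism,
        medium=cfg.medium,
        vessel=cfg.vessel,
        flow=cfg.flow,
        calibration=cfg.calibration,
        acquisition=cfg.acquisition,
        initial_state=to_initial_state(channel),
        seed=channel_seed(global_seed, channel.channel_id),
        channel=channel.channel_id,
    )


def run_channel(
    channel: ChannelModel,
    global_seed: int = 0,
    *,
    event_exact: bool = False,
    cycle_cap: int = 100,
) -> ExperimentLog:
    """Simulate one channel closed-loop from its config block."""
    rig = build_rig(channel, global_seed)
    return run_experiment(
        rig, to_experiment_config(channel), event_exact=event_exact, cycle_cap=cycle_cap
    )


def run_config(
    cfg: RunConfig, *, event_exact: bool = False, cycle_cap: int = 100
) -> dict[int, ExperimentLog]:
    """Run every channel of a config; returns logs keyed by channel id."""
    return {
        ch.channel_id: run_channel(
            ch, cfg.seed, event_exact=event_exact, cycle_cap=cycle_cap
        )
        for ch in cfg.channels
    }


def run_preset(
    name: str,
    duration_h: float | None = None,
    seed: int = 0,
    *,
    event_exact: bool = False,
) -> ExperimentLog:
    """Convenience: simulate a named single-channel preset."""
    cfg = preset(name, duration_h=duration_h, seed=seed)
    return run_channel(cfg.channels[0], cfg.seed, event_exact=event_exact)
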