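import math

import pytest
from hypothesis import settings

import microstat as ms

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mflorum_grid_log() -> ms.ExperimentLog:
    """12 h phenol-red turbidostat, real-time feedback band 11.5-12 %,
    sampled on the 0.5 s grid with 2-point averaging, noise off."""
    return ms.run_preset("mflorum-like", duration_h=12.0)


@pytest.fixture(scope="session")
def mflorum_exact_log() -> ms.ExperimentLog:
    """Same run with event-exact threshold detection."""
    return ms.run_preset("mflorum-like", duration_h=12.0, event_exact=True)


@pytest.fixture(scope="session")
def ecoli_grid_log() -> ms.ExperimentLog:
    """12 h turbidity culture, threshold-activated at 50 % (3 s, 1 cycle)."""
    return ms.run_preset("ecoli-like", duration_h=12.0)


@pytest.fixture(scope="session")
def ecoli_exact_log() -> ms.ExperimentLog:
    return ms.run_preset("ecoli-like", duration_h=12.0, event_exact=True)


def first_trigger_time(log: ms.ExperimentLog) -> float:
    starts = log.rows[log.rows["event"] == "refresh_start"]
    assert len(starts) > 0, "expected at least one refresh activation"
    return float(starts["time_s"].iloc[0])


@pytest.fixture(scope="session")
def chemostat_organism() -> ms.OrganismParams:
    """Nutrient-limited fixture: Ks large enough that the chemostat
    steady state sits well inside the Monod curve."""
    return ms.OrganismParams(
        mu_max=math.log(2.0) / 0.48,
        Ks=2.0,
        yield_Y=1e8,
        optics=ms.OpticalModelParams(k_cell=2e-9),
    )
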