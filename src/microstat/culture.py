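"""Virtual culture dynamics.

The simulator stands in for a live vessel: Monod-limited growth,
substrate depletion, metabolic acid production driving medium pH, and
the volumetric mixing caused by dilution. Monod kinetics is the minimal
closure that exhibits both regimes the rig operates in — at saturating
substrate (S >> Ks) cells grow at ``mu_max`` (turbidostat regime), and
under nutrient limitation growth is pinned to the dilution rate
(chemostat regime).

State variables (:class:`CultureState`):

* ``t``   — time, hours
* ``V``   — liquid volume, mL
* ``X``   — viable cell density, CFU/mL
* ``S``   — limiting substrate, g/L
* ``C_acid`` — lumped metabolic acid, arbitrary acid units per mL

pH is *derived*, not stored: ``pH = max(pH_floor, pH0 - C_acid/beta)``
with ``beta`` the medium's buffer capacity. Acid is mixed volumetrically
like any other solute; mixing pH values directly would be wrong because
pH is logarithmic.

Growth is integrated with a fixed-step classical Runge-Kutta (RK4)
scheme — deterministic and reproducible, no adaptive stepping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ConfigurationError, DomainError, FluidicsError, IntegrationError, StateError
from .optics import OpticalModelParams

__all__ = [
    "OrganismParams",
    "MediumSpec",
    "CultureState",
    "PH_FLOOR",
    "DEFAULT_MAX_STEP_H",
    "specific_growth_rate",
    "step_growth",
    "advance",
    "mix_in",
    "draw_off",
    "culture_pH",
    "monod_steady_state",
]

#: pH never drops below this in the model (strong acidification saturates).
PH_FLOOR = 4.0

#: Default RK4 step cap: 36 s expressed in hours.
DEFAULT_MAX_STEP_H = 36.0 / 3600.0


@dataclass(frozen=True)
class OrganismParams:
    """Kinetic and optical parameters of a (virtual) organism.

    ``mu_max`` per hour, ``Ks`` g/L, ``yield_Y`` cells produced per gram
    of substrate, ``q_acid`` acid units produced per cell grown.
    """

    mu_max: float
    Ks: float
    yield_Y: float
    q_acid: float = 0.0
    optics: OpticalModelParams = OpticalModelParams()

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ConfigurationError("mu_max must be > 0")
        if not self.Ks > 0:
            raise ConfigurationError("Ks must be > 0")
        if not self.yield_Y > 0:
            raise ConfigurationError("yield_Y must be > 0")
        if self.q_acid < 0:
            raise ConfigurationError("q_acid must be >= 0")

    @property
    def doubling_time(self) -> float:
        """Minimum doubling time, hours (ln 2 / mu_max)."""
        return math.log(2.0) / self.mu_max


@dataclass(frozen=True)
class MediumSpec:
    """Fresh-medium composition relevant to the model."""

    S0: float
    pH0: float = 7.0
    buffer_capacity: float = 1.0
    phenol_red: bool = False

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise ConfigurationError("S0 must be >= 0")
        if not self.buffer_capacity > 0:
            raise ConfigurationError("buffer_capacity must be > 0")


@dataclass(frozen=True)
class CultureState:
    """Evolving state of one culture vessel."""

    t: float
    V: float
    X: float
    S: float
    C_acid: float = 0.0

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise StateError("volume must be > 0")
        if self.X < 0 or self.S < 0 or self.C_acid < 0:
            raise StateError("X, S and C_acid must be >= 0")


def culture_pH(state: CultureState, medium: MediumSpec, pH_floor: float = PH_FLOOR) -> float:
    """Medium pH implied by the accumulated acid load."""
    return max(pH_floor, medium.pH0 - state.C_acid / medium.buffer_capacity)


def specific_growth_rate(S: float, org: OrganismParams) -> float:
    """Monod specific growth rate mu(S) = mu_max * S / (Ks + S), per hour."""
    if S < 0:
        raise DomainError("substrate concentration must be >= 0")
    return org.mu_max * S / (org.Ks + S)


def _derivatives(X: float, S: float, org: OrganismParams):
    mu = specific_growth_rate(max(S, 0.0), org)
    dX = mu * X
    return dX, -dX / org.yield_Y, org.q_acid * dX


def step_growth(
    state: CultureState, dt: float, org: OrganismParams, medium: MediumSpec
) -> CultureState:
    """Advance growth by one RK4 step of ``dt`` hours (no dilution).

    dX/dt = mu(S) X,  dS/dt = -mu(S) X / Y,  dC/dt = q_acid mu(S) X.
    Substrate is floored at zero after the step.
    """
    if not dt > 0:
        raise DomainError("dt must be > 0")
    X, S, C = state.X, state.S, state.C_acid
    k1 = _derivatives(X, S, org)
    k2 = _derivatives(X + 0.5 * dt * k1[0], S + 0.5 * dt * k1[1], org)
    k3 = _derivatives(X + 0.5 * dt * k2[0], S + 0.5 * dt * k2[1], org)
    k4 = _derivatives(X + dt * k3[0], S + dt * k3[1], org)
    Xn = X + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    Sn = S + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    Cn = C + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    if not (math.isfinite(Xn) and math.isfinite(Sn) and math.isfinite(Cn)):
        raise IntegrationError(f"non-finite state after step at t={state.t}")
    return replace(state, t=state.t + dt, X=max(Xn, 0.0), S=max(Sn, 0.0), C_acid=max(Cn, 0.0))


def advance(
    state: CultureState,
    hours: float,
    org: OrganismParams,
    medium: MediumSpec,
    max_step: float = DEFAULT_MAX_STEP_H,
) -> CultureState:
    """Integrate growth over ``hours`` with fixed RK4 steps <= ``max_step``."""
    if hours < 0:
        raise DomainError("hours must be >= 0")
    if hours == 0:
        return state
    n = max(1, math.ceil(hours / max_step))
    dt = hours / n
    for _ in range(n):
        state = step_growth(state, dt, org, medium)
    return state


def mix_in(state: CultureState, dV: float, medium: MediumSpec) -> CultureState:
    """Add ``dV`` mL of fresh medium and mix instantaneously.

    Solutes (cells, substrate, acid) combine volumetrically; fresh
    medium carries substrate S0, no cells and no acid.
    """
    if dV < 0:
        raise DomainError("dV must be >= 0")
    if dV == 0:
        return state
    Vn = state.V + dV
    return replace(
        state,
        V=Vn,
        X=state.X * state.V / Vn,
        S=(state.S * state.V + medium.S0 * dV) / Vn,
        C_acid=state.C_acid * state.V / Vn,
    )


def draw_off(state: CultureState, V_target: float) -> CultureState:
    """Remove well-mixed culture down to ``V_target`` mL.

    Concentrations are invariant; only the volume changes.
    """
    if not 0 < V_target <= state.V + 1e-12:
        raise FluidicsError(
            f"cannot draw off to {V_target} mL from {state.V} mL"
        )
    return replace(state, V=min(V_target, state.V))


def monod_steady_state(D: float, org: OrganismParams, medium: MediumSpec):
    """Closed-form chemostat steady state at dilution rate ``D`` (per hour).

    Returns ``(S_star, X_star)`` with ``S* = Ks D / (mu_max - D)`` and
    ``X* = Y (S0 - S*)``. Only defined for ``0 < D < mu_max``.
    """
    if not 0 < D < org.mu_max:
        raise DomainError("steady state requires 0 < D < mu_max (else washout)")
    S_star = org.Ks * D / (org.mu_max - D)
    if S_star > medium.S0:
        raise DomainError("feed substrate too low to sustain this dilution rate")
    return S_star, org.yield_Y * (medium.S0 - S_star)
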