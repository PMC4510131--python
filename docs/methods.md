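# Methods

This note records the models behind the simulator, the defaults and why
they were chosen, the numerical choices, and what the simulations do
and do not establish about a physical rig.

## Optical model

Relative transmittance is defined operationally by the two-point
calibration (dark = 0 %, blank = 100 %); the forward model maps culture
state to a *true* transmittance via additive absorbances at 560 nm:

* turbidity: `A_cells = k_cell · X · path_length`, linear in viable
  density. `k_cell` is an empirical per-rig coefficient; the presets use
  2×10⁻⁹ absorbance per (CFU/mL)·cm, which puts 1.5×10⁸ CFU/mL at 50 %
  transmittance — a plausible mid-exponential operating point.
* phenol red: piecewise linear in pH between `pH_lo = 6` and
  `pH_hi = 7`, flat outside. The linear window mirrors where the
  indicator's response is observed to be linear; extrapolating flat is
  deliberate — the model should not invent sensitivity where the
  indicator has none. The preset endpoints place fresh medium (pH ≥ 7)
  at 8 % transmittance and fully acidified medium (pH ≤ 6) at 16 %,
  the span a mollicute batch culture traverses; the absorbance
  difference is then exactly log10(2).

Out-of-range transmittances (< 0 % or > 100 %) are flagged, never
clipped: silent clipping would mask calibration drift. Detector noise
is additive Gaussian in raw-signal space (where a photoreceiver's noise
lives), before calibration; the LED/receiver synchronization that
suppresses ambient light is treated as a solved hardware property and
is represented only by the `noise_sd` knob. The boxcar average is a
moving window (value *k* = mean of the last min(*k*, *n*) samples); a
block average would be the other defensible reading of "averaging over
n points", and anyone matching the original acquisition software
bit-for-bit should check which it uses.

## Culture model

Monod kinetics is the minimal growth law exhibiting both operating
regimes: at saturating substrate (S ≫ K_s) growth runs at μ_max
(turbidostat regime), under limitation growth is set by dilution
(chemostat regime, steady state S* = K_s·D/(μ_max − D),
X* = Y·(S0 − S*)). State is (V, X, S, C_acid); pH is derived,
`pH = max(4, pH0 − C_acid/β)`, and acid is mixed volumetrically like
any solute — mixing pH values directly would be wrong because pH is
logarithmic. The floor at pH 4 caps acidification far below the
indicator window, where it no longer affects the optics.

Integration is classical RK4 with a fixed step of at most 36 s
(`min(sample period, 36 s)` inside the event loop): deterministic and
reproducible, no adaptive stepping. Halving the step changes a 12 h
trajectory endpoint by < 10⁻⁶ relative (tested), so integrator error is
negligible against every tolerance used.

Preset kinetic parameters are fixtures, not measurements. Growth rates
are anchored to the observed generation counts of the reference
experiments: μ_max = ln2/0.48 h⁻¹ for the fast turbidity organism (~25
doublings in 12 h) and ln2/0.6 h⁻¹ for the phenol-red organism (~20),
with the slow turbidity preset at ln2/1.5 h⁻¹. K_s = 0.05 g/L and
S0 = 10 g/L keep substrate saturating in the triggered modes, so the
turbidostat invariant (realized μ within 2 % of μ_max between
refreshes) holds by construction of the regime, not by tuning. Yields
(1–2×10⁸ cells/g) set the substrate drain so a 12 h closed-loop run
neither exhausts the feed nor leaves the Monod regime. The chemostat
tests use a separate nutrient-limited fixture (K_s = 2 g/L) so the
steady state sits well inside the Monod curve and the per-pulse
substrate jump stays ≪ S*; they measure the end state after ≥ 20/D
hours with pulse period ≤ 0.002/D.

Not modeled (out of scope by design): the post-peak transmittance
decline from cell agglomeration in mollicute cultures — simulations
target the pre-agglomeration regime; death phase, oxygen transfer and
temperature dynamics (temperature is delegated to the room/incubator).

## Fluidics

Delivered volume is `rate · max(0, pinch_time − dead_time)`; the preset
rate is 1 mL/s with zero dead time, but the dead time is exposed because
real tubing has lag and a flow calibration naturally fits an intercept.
Delivery is applied instantaneously at cycle end with no growth during
the valve-open seconds: pinch times (≤ 35 s) are two orders of
magnitude below doubling times, so the error is negligible and the
model stays event-driven. The overflow guard — a single cycle may never
deliver more than capacity − working volume — is checked before any
state change, and mode validation rejects configured pinch times above
that bound, so no sequence of valid cycles can overflow the vessel.
Flow-rate variation with medium-bottle fill level is assumed absent
(constant per calibration).

## Controller

Decisions are made on the boxcar-filtered calibrated transmittance,
every sample period. Threshold comparisons are inclusive (≥/≤ at the
boundary), so in noise-free runs the trigger value itself is the
recorded extremum. Polarity is an explicit config field rather than
being inferred from threshold ordering, because the phenol-red signal
inverts the growth direction and inference is ambiguous in
time-interval mode. During a multi-cycle refresh the controller
re-measures after each cycle (one sample period settle) before deciding
to continue. The threshold-activated mode re-arms immediately after its
n cycles; no refractory period. Time-interval refreshes are scheduled
from the arming instant, with threshold-terminated refreshes capped at
a configurable cycle count (default 100) since a stop value below the
fresh-medium transmittance is unreachable. Channels are fully
independent event loops; the hardware contract is synchronous and
real-time pacing lives in the driver's `sleep` (the simulated rig
advances a virtual clock instead).

**Event-exact mode** is a simulation-only refinement: the rig supports
state snapshot and pure look-ahead, so the controller can locate a
threshold crossing inside a sample interval by root finding (Brent) and
trim the final dilution cycle so the signal lands exactly on the stop
threshold. It requires noise off and makes decisions on the
instantaneous reading, since the boxcar's group delay is precisely the
sampling artifact the mode removes. It exists to separate the
controller's intrinsic setpoint behaviour from sampling-grid
quantization; physical drivers cannot provide it. A residual tolerance
of 10⁻⁹ % absorbs the root-finder's float error on the trimmed cycle.

## Logs, configs, reproducibility

Logs are a single time-ordered CSV mixing sample rows and event rows
(refresh start/cycle/stop, abort), with a JSON sidecar carrying the
config snapshot, seed and software version; every transmittance is
recomputable from the raw column plus the stored calibration. Configs
are strict YAML (unknown keys rejected, cross-field invariants checked
at load). Identical config + seed produces byte-identical logs; the
per-channel noise seed is derived as `(seed + 7919·channel) mod 2³¹−1`.

## Analysis conventions

Ordinary least squares with Pearson r throughout; a constant response
is reported as slope 0 with r = 0 rather than an undefined correlation.
Quartiles interpolate linearly between order statistics, and box-plot
whiskers extend to the most extreme datum within 1.5 IQR of the
quartiles but never retreat inside the (interpolated) box. Exclusion
windows for the calibration fits (exponential-phase transmittance
range, indicator pH window) are explicit parameters because the
exclusions are organism-specific judgments. The transmittance-vs-pH
relation of the forward model is exponential in pH (linear in
absorbance), so a straight-line fit over the pH 6–7 window is a
linearization: its r² exceeds 0.99 and its slope matches
−ln10·ΔA·T̄ within 5 %, which is the sense in which the relation "is
linear" over that window.

Generation counting sums log2((w+v)/w) over refresh events — at steady
state dilution exactly balances growth. For non-steady logs with a
turbidity readout the net density change log2(A_end/A_start) is added
and the estimate is flagged; for phenol-red logs no correction is
possible from transmittance alone (absorbance tracks accumulated acid,
not density), so the flagged value is the dilution bookkeeping only.

## What the simulations do and do not show

Passing closed-loop tests shows the *control logic* holds its setpoints
given the stated optical and kinetic models, and that the analysis
recovers generator parameters from data those models produce. It does
not validate the models against a live culture: real rigs add biofilm
on the vessel wall (degrading both optics and dilution over days),
agglomeration optics, detector drift between calibrations, and flow
variability — none of which the virtual rig emulates. Empirical
correlation strengths (e.g. r² of transmittance vs log CFU on a real
culture) are therefore checked as properties on synthetic data, not as
reproduced numbers.

## Problem sizes

The reference closed-loop runs simulate 12 h at their printed sample
periods (0.5 s / 86 400 samples for the feedback run, 5 s / 8 640 for
the threshold run); chemostat convergence and washout use 10 s pulses
over 30 h and 24 h. These sizes make every setpoint and steady-state
check a matter of seconds on one CPU.
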