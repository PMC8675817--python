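# Methods

## The control problem

During and after cardiac surgery, mean arterial pressure (MAP) is regulated
by infusing the vasodilator sodium nitroprusside (SNP). The package models
the patient as a linear time-invariant transfer function from infusion rate
(ml/h) to pressure change, with three drug-effect time constants, a drug
recirculation fraction α, and — dominating everything else — a transport
delay of 60 s between a change at the pump and its effect on measured
pressure:

```
ΔMAP(s)/SNP(s) = K (1 + T3 s) e^{-θs} / [((1 + T3 s)(1 + T2 s) − α)(1 + T1 s)]
```

The canonical patient instance is stored directly in expanded polynomial
form, `5(1+30s)e^{-60s} / (1 + 130s + 4600s² + 30000s³)`, because the
individual `(K, T1…T3, α)` values that generate it are not uniquely
determined from the composite polynomial and we deliberately do not
reverse-engineer a factorization. Its poles sit at −0.119, −0.020 and
−0.014 s⁻¹ (time constants ≈ 8.4, 50 and 72 s): a slow plant behind a long
delay.

Outputs are normalized: 1 means "the pressure moved the full way from the
initial to the target value". `DisplayMapping` renders absolute mmHg as
`MAP = MAP_initial + (MAP_target − MAP_initial)·y`, defaults 40 → 80 mmHg.
The normalized loop always starts at rest; the mapping is presentation only.

## Discretization and simulation

Zero-order-hold discretization is exact (matrix exponential via
`scipy.signal.cont2discrete`); the delay becomes `d = round(θ/Ts)` samples
(a warning is raised when rounding is not exact — no fractional-delay
approximation is attempted). At Ts = 1 s the canonical model gives the
difference equation

```
y(k) = −a2 y(k−1) − a1 y(k−2) − a0 y(k−3) + b2 u(k−61) + b1 u(k−62) + b0 u(k−63)
b = (0.002403, −1.543e−5, −0.002233),  a = (−2.854, 2.712, −0.8578),  d = 60
```

`simulate` implements this recursion for arbitrary orders and histories;
tests verify it against `scipy.signal.lfilter`, against linearity, time
shift and DC-gain identities. Disturbances are output-additive (they
corrupt the measurement, not the drug path).

## The predictive controller

At each sample the controller minimizes

```
J = Σ_{i=1..P} μ_i (ŷ(t+i|t) − w(t+i))² + Σ_{i=1..M} λ_i Δu(t+i)²
```

over M infusion-rate increments, applies the first and re-plans. Defaults:
P = 20, M = 2, μ = 1, λ = 0.1, u ∈ [0, 2] ml/h. The increment
parameterization provides integral action; the lower bound 0 is physical
(an infusion cannot be withdrawn) and the upper bound is the pump limit.

**Dead-time handling.** With d = 60 and P = 20, a literal cost over
ŷ(t+1..t+20) is degenerate: those outputs are already fixed by past inputs
and no candidate move changes them (a property test demonstrates this). The
default therefore shifts the costed window past the delay, to
ŷ(t+d+1 .. t+d+P) — functionally a Smith-predictor arrangement, and the
only reading under which varying P changes anything. The literal variant
stays available behind `horizon_shift=False` for study.

**Feedback.** The controller runs an internal replica of the plant driven
by the applied inputs; the bias `measured − model output` is added to all
predictions (classic dynamic-matrix-control correction, constant over the
horizon). With an exact model and no disturbance the bias is identically
zero; under an output disturbance it is the loop's only feedback path. A
constant-bias extrapolation is deliberately simple: against a sinusoid
whose period (100 s) is comparable to the delay (60 s) the correction is
badly phased and rejection is poor — visible in the disturbance study.

**Evaluation path.** Because the plant is linear, a candidate population is
scored as `free response + G·Δu` with a precomputed P×M step-response
matrix — algebraically identical to simulating each candidate (a test pins
the equivalence to 1e−12) and fast enough to score 100 chromosomes as one
matrix product. Candidate cumulative rates are clipped to the pump limits
before costing, so every evaluated chromosome is feasible; the applied rate
is clipped again as a hard guarantee.

## Optimizers

*Genetic algorithm* (the study optimizer): real-coded chromosomes of the M
move increments; tournament selection of size 2; whole-arithmetic blend
crossover with probability 0.7; per-gene Gaussian mutation with probability
0.005 and σ = 10 % of the gene's bound width; one elite; population 100 for
10 generations; full generational replacement. The zero-move chromosome is
always seeded into generation 0, so the accepted move never costs more than
doing nothing (asserted every step of every run). The per-gene bounds are
`[u_min − u_prev, u_max − u_prev]`.

*Grid oracle*: exhaustive scoring of a regular grid (101 points per gene by
default), ties broken toward the lexicographically smallest chromosome.
Used both as the deterministic "plain MPC" baseline and as the verification
oracle: on 50 random mid-transient one-step objectives the GA lands within
5 % of the grid optimum (relative to the do-nothing cost) in ≥ 90 % of
cases.

*Particle swarm*: global-best PSO, swarm 30 × 33 iterations (budget-matched
to the GA's ≈ 1000 evaluations), inertia 0.7, cognitive = social = 1.5,
velocity clamped to half the box, bound reflection.

*PID*: positional form on the same normalized error, trapezoidal integral,
derivative on error, clamped to the pump limits with conditional-integration
anti-windup. Gains come from the classic Ziegler-Nichols ultimate-cycle
table (Kp = 0.6 Ku, Ki = 1.2 Ku/Tu, Kd = 0.075 Ku Tu) with Ku, Tu computed
from the discrete frequency response; the −180° crossing search stops just
short of Nyquist, where every sampled real-pole plant touches −180° without
a usable ultimate cycle.

## Performance indices and the error convention

Over a window of N samples: `IAE = Σ|e|Ts`, `ISE = Σe²Ts`,
`MSE = ISE/(N·Ts)`, so `ISE = MSE·N·Ts` by construction. The standard
window for all studies is 200 samples at Ts = 1 s.

Two error conventions exist. Raw: `e(k) = r(k) − y(k)` from t = 0. Because
no causal controller can move the output during the first d samples, the
raw index of a step scenario carries an irreducible ≈ d·amplitude floor
(≈ 60 here) that is identical for every controller. The headline indices
are therefore **delay-aligned**: `e(k) = r(k−d) − y(k)`, charging the
controller only for error it could have influenced. Every scenario report
contains both variants.

**The saturation floor.** Even delay-aligned indices have a hard lower
bound: the output can never rise faster than the plant driven flat-out at
u_max, so until `u_max·s(t)` first reaches the set-point the error is at
least `1 − u_max·s(t)`. `actuator_limited_bounds` integrates this floor;
for the canonical plant and u_max = 2 ml/h it gives IAE ≥ 12.0 and
ISE ≥ 9.2 (set-point first reachable after 19.7 s of full drive). The
GA-MPC loop reports IAE ≈ 14.4, about 20 % above the floor — the residual
is the back-off needed to avoid overshoot with λ-penalized moves. Published
index values substantially below this floor for the same plant and input
limit are not reachable by any admissible controller and are not reproduced
here.

## Scenario conventions

* Reference: normalized unit step at t = 0, last-value hold beyond the
  known window.
* Disturbance: sinusoid specified in display units (10 mmHg ⇒ 0.25
  normalized through the 40 mmHg display span), period 100 s (a slow
  drug-effect oscillation; no period is canonical, so it is configurable),
  entering additively at the measured output from t = 0.
* Determinism: one `numpy` Generator seeded per run feeds the optimizer
  across steps; identical seeds give bit-identical histories and CSV files.
  Sweeps reuse the same seed per row.
* Problem sizes: 200-sample windows, medians over 10 seeds for stochastic
  quantities — large enough that the medians move by well under a percent
  between seed sets, small enough that the whole study suite runs in
  minutes on one core.

## Heart-muscle mechanics

Muscle, transducer and infusion set are lumped into one rotational
mass-spring-damper (inertia J, viscosity B, stiffness k). A pressure surge
applies torque Mx against the internally generated torque with resting
component M0; eliminating the damper-side angle yields

```
(BJ/k) θ''' + J θ'' + B θ' = Mx(t) − M0(t)
```

i.e. `θ(s)/ΔM(s) = 1/(s((BJ/k)s² + Js + B))`. Only the torque difference
matters (tested); a constant difference A settles the angular rate at A/B
while the angle ramps (pure integrator). No numeric J, B, k are canonical;
the defaults are 1 (a dimensionless structural study) and all three are
configurable. Integration restarts the LSODA solver at every sample so the
held-input discontinuities never fall inside a step, with an automatic
switch to the L-stable Radau method in the stiff rigid-spring regime
(k/B·Ts > 10³); the result matches the ZOH-discretized transfer function to
1e−6 and the k → ∞ limit reduces to the second-order rigid model. The
module is standalone: no coupling law into the pressure loop is defined, so
none is invented; the loop's infusion signal can be fed in as Mx for
illustration only.

## Known limitations

* Single-input single-output, exact-model assumption: no plant-model
  mismatch, no inter-patient variability beyond the exposed parameters, no
  drug interaction.
* The constant-bias disturbance model is the weakest link: periodic
  disturbances near the delay timescale are rejected poorly, and a
  harmonic disturbance observer would do better.
* Synthetic signals only (steps and sinusoids); real MAP telemetry has
  beat-to-beat noise, baroreflex dynamics and actuator quantization that
  the generator does not emulate, so passing tests certify the algorithms,
  not clinical performance.
* The Ziegler-Nichols PID is a textbook baseline; dead-time-aware PID
  tuning would narrow (not close) the gap to the predictive controllers.
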