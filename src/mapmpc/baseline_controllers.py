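"""Comparison controllers: Ziegler-Nichols PID and PSO-driven MPC.

Three baselines bracket the GA-driven predictive controller:

* ``grid_mpc`` -- identical cost and horizons, optimized by the exhaustive
  grid oracle (deterministic; isolates the optimizer comparison),
* ``pso_mpc`` -- identical cost, optimized by global-best particle-swarm
  search with an evaluation budget matched to the GA's,
* ``pid`` -- a positional PID on the same normalized error, tuned by the
  classic Ziegler-Nichols ultimate-cycle rules and clamped to the same pump
  limits with conditional-integration anti-windup.

The paper trail for the PID is thin by design: no gains are available for the
published comparison, so the ultimate gain and period are computed here from
the discrete plant's frequency response and only the qualitative ranking of
the controllers is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ga_optimizer import OptResult, _check_bounds
from .mpc_controller import ClosedLoopHistory, extend_reference
from .patient_model import DiscretePatientModel, PlantSimulator

__all__ = [
    "PIDGains",
    "PIDState",
    "PSOConfig",
    "pid_step",
    "pso_optimize",
    "run_pid_loop",
    "ultimate_cycle",
    "zn_pid_from_ultimate",
    "ziegler_nichols_tune",
]


# ---------------------------------------------------------------- PID

@dataclass(frozen=True)
class PIDGains:
    Kp: float
    Ki: float
    Kd: float

    def __post_init__(self):
        if not all(np.isfinite([self.Kp, self.Ki, self.Kd])):
            raise ValueError("PID gains must be finite")


@dataclass
class PIDState:
    integral: float = 0.0
    prev_error: float = 0.0
    primed: bool = False  # first call has no derivative history


def pid_step(
    gains: PIDGains,
    error: float,
    state: PIDState,
    Ts: float,
    u_min: float = 0.0,
    u_max: float = 2.0,
) -> float:
    """One positional-PID update; mutates ``state``; returns the clamped output.

    Trapezoidal integral, derivative on the error, conditional integration:
    the integral is frozen whenever the unsaturated output is pushing further
    past an active limit.
    """
    deriv = 0.0 if not state.primed else (error - state.prev_error) / Ts
    trial_int = state.integral + 0.5 * Ts * (error + state.prev_error) \
        if state.primed else state.integral + Ts * error
    u_unsat = gains.Kp * error + gains.Ki * trial_int + gains.Kd * deriv
    windup = (u_unsat > u_max and error > 0) or (u_unsat < u_min and error < 0)
    if not windup:
        state.integral = trial_int
        u_unsat = gains.Kp * error + gains.Ki * state.integral + gains.Kd * deriv
    state.prev_error = error
    state.primed = True
    return float(np.clip(u_unsat, u_min, u_max))


def ultimate_cycle(dmodel: DiscretePatientModel, n_grid: int = 20000) -> tuple:
    """Ultimate gain Ku and period Tu from the discrete frequency response.

    Finds the first frequency where the open-loop phase (rational part plus
    the sample delay) crosses -180 degrees; Ku is the proportional gain that
    puts the loop on the stability boundary there, Tu the oscillation period.
    Raises if the phase never reaches -180 degrees (e.g. a delay-free
    first-order lag), in which case reaction-curve tuning is the fallback.
    """
    Ts = dmodel.Ts
    # stop short of Nyquist: every sampled real-pole plant touches -180 deg
    # exactly there, which is not a usable ultimate cycle
    w = np.linspace(1e-6 / Ts, 0.999 * np.pi / Ts, n_grid)
    z = np.exp(1j * w * Ts)
    num = np.polyval(dmodel.num, z)
    den = np.polyval(dmodel.den, z)
    h = num / den
    phase = np.unwrap(np.angle(h)) - w * Ts * dmodel.delay
    below = np.nonzero(phase <= -np.pi)[0]
    if len(below) == 0:
        raise ValueError(
            "phase never reaches -180 degrees: no finite ultimate gain; "
            "use reaction-curve (open-loop step) tuning instead"
        )
    i = below[0]
    if i == 0:
        raise ValueError("phase crossing at the lowest probed frequency; "
                         "the model looks degenerate")
    # linear interpolation of the crossing frequency
    f = (-np.pi - phase[i - 1]) / (phase[i] - phase[i - 1])
    wu = w[i - 1] + f * (w[i] - w[i - 1])
    zu = np.exp(1j * wu * Ts)
    mag = np.abs(np.polyval(dmodel.num, zu) / np.polyval(dmodel.den, zu))
    Ku = 1.0 / mag
    Tu = 2.0 * np.pi / wu
    return float(Ku), float(Tu)


def zn_pid_from_ultimate(Ku: float, Tu: float) -> PIDGains:
    """Classic Ziegler-Nichols PID table: Kp=0.6Ku, Ki=1.2Ku/Tu, Kd=0.075KuTu."""
    return PIDGains(Kp=0.6 * Ku, Ki=1.2 * Ku / Tu, Kd=0.075 * Ku * Tu)


def ziegler_nichols_tune(dmodel: DiscretePatientModel) -> PIDGains:
    """Ultimate-cycle Ziegler-Nichols tuning of the discrete plant."""
    Ku, Tu = ultimate_cycle(dmodel)
    return zn_pid_from_ultimate(Ku, Tu)


def run_pid_loop(
    dmodel: DiscretePatientModel,
    reference,
    disturbance,
    gains: PIDGains,
    n_samples: int,
    u_min: float = 0.0,
    u_max: float = 2.0,
) -> ClosedLoopHistory:
    """Closed loop under the PID baseline (deterministic, no optimizer)."""
    ref = extend_reference(reference, n_samples)
    dist = np.zeros(n_samples) if disturbance is None else np.asarray(
        disturbance, dtype=float
    )
    if len(dist) < n_samples:
        raise ValueError("disturbance shorter than the simulation window")
    plant = PlantSimulator(dmodel)
    state = PIDState()
    y_out = np.empty(n_samples)
    u_out = np.empty(n_samples)
    for t in range(n_samples):
        y_meas = plant.output() + dist[t]
        e = ref[t] - y_meas
        u = pid_step(gains, e, state, dmodel.Ts, u_min, u_max)
        plant.advance(u)
        y_out[t] = y_meas
        u_out[t] = u
    return ClosedLoopHistory(
        Ts=dmodel.Ts,
        r=ref[:n_samples].copy(),
        y=y_out,
        u=u_out,
        d=dist[:n_samples].copy(),
        cost=np.zeros(n_samples),
    )


# ---------------------------------------------------------------- PSO

@dataclass(frozen=True)
class PSOConfig:
    """Global-best particle swarm, budget-matched to the GA (30 x 33 ~ 100 x 10)."""

    swarm: int = 30
    iterations: int = 33
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    v_max_frac: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.swarm < 2:
            raise ValueError("swarm size must be at least 2")
        if self.iterations < 1:
            raise ValueError("at least one iteration is required")
        if min(self.inertia, self.cognitive, self.social) < 0:
            raise ValueError("PSO coefficients must be nonnegative")


def pso_optimize(
    objective,
    bounds,
    cfg: PSOConfig | None = None,
    rng: np.random.Generator | None = None,
    seeds=None,
) -> OptResult:
    """Minimize over a box by global-best PSO with velocity clamping and
    bound reflection; deterministic given ``rng`` (or ``cfg.seed``)."""
    cfg = cfg or PSOConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = _check_bounds(bounds)
    m = len(lo)
    span = hi - lo
    vmax = cfg.v_max_frac * span

    x = rng.uniform(lo, hi, size=(cfg.swarm, m))
    if seeds is not None:
        seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
        k = min(len(seeds), cfg.swarm)
        x[:k] = np.clip(seeds[:k], lo, hi)
    v = rng.uniform(-vmax, vmax, size=(cfg.swarm, m))

    cost = np.asarray(objective(x), dtype=float)
    if not np.all(np.isfinite(cost)):
        raise ValueError(
            f"objective returned a non-finite value at {x[~np.isfinite(cost)][0]}"
        )
    pbest_x = x.copy()
    pbest_c = cost.copy()
    g = int(np.argmin(pbest_c))
    trace = [float(pbest_c[g])]
    n_eval = cfg.swarm

    for _ in range(cfg.iterations):
        r1 = rng.random((cfg.swarm, m))
        r2 = rng.random((cfg.swarm, m))
        v = (
            cfg.inertia * v
            + cfg.cognitive * r1 * (pbest_x - x)
            + cfg.social * r2 * (pbest_x[g] - x)
        )
        v = np.clip(v, -vmax, vmax)
        x = x + v
        # reflect off the box walls
        over = x > hi
        under = x < lo
        x = np.where(over, 2 * hi - x, x)
        x = np.where(under, 2 * lo - x, x)
        x = np.clip(x, lo, hi)  # guard double-bounce
        v = np.where(over | under, -v, v)
        cost = np.asarray(objective(x), dtype=float)
        n_eval += cfg.swarm
        if not np.all(np.isfinite(cost)):
            raise ValueError(
                "objective returned a non-finite value at "
                f"{x[~np.isfinite(cost)][0]}"
            )
        better = cost < pbest_c
        pbest_x[better] = x[better]
        pbest_c[better] = cost[better]
        g = int(np.argmin(pbest_c))
        trace.append(float(pbest_c[g]))
    return OptResult(
        best_x=pbest_x[g].copy(),
        best_cost=float(pbest_c[g]),
        trace=np.array(trace),
        n_evaluations=n_eval,
    )
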