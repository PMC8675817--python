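"""Receding-horizon predictive control of the dead-time patient model.

At every sample the controller minimizes

    J = sum_{i=1..P} mu_i (yhat(t+i|t) - w(t+i))^2
      + sum_{i=1..M} lam_i (Delta u(t+i))^2

over M future infusion-rate increments, applies only the first one, and slides
the window forward.  The increment parameterization gives the loop integral
action; the applied rate is hard-clipped to the pump limits.

Dead-time handling: with a transport delay of d samples, outputs at
t+1 .. t+d are already fixed by past inputs, so a literal cost over
yhat(t+1..t+P) with P <= d is degenerate (no candidate move changes it).  With
``horizon_shift=True`` (the default) the P costed predictions are
yhat(t+d+1 .. t+d+P) -- the first instants the current move can reach,
functionally a Smith-predictor arrangement.  The literal reading stays
available behind the flag.

Feedback enters through an additive output-bias estimate (measured output
minus the controller's internal model output) held constant over the horizon,
the classic dynamic-matrix-control correction; with an exact model and no
disturbance the bias is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patient_model import (
    DiscretePatientModel,
    DisplayMapping,
    InitialHistory,
    PlantSimulator,
    simulate,
)

__all__ = [
    "ClosedLoopHistory",
    "ControllerState",
    "MPCConfig",
    "StepResult",
    "control_step",
    "cost",
    "extend_reference",
    "move_bounds",
    "predict",
    "run_closed_loop",
    "step_response_matrix",
]


@dataclass(frozen=True)
class MPCConfig:
    """Horizons, weights and input limits of the predictive controller.

    ``mu``/``lam`` may be scalars (uniform weights) or per-step sequences of
    lengths P and M.  ``u_min`` is 0 by default: an infusion cannot be
    withdrawn.  ``u_max`` is the pump limit, 2 ml/h.
    """

    P: int = 20
    M: int = 2
    mu: float | tuple = 1.0
    lam: float | tuple = 0.1
    u_min: float = 0.0
    u_max: float = 2.0
    horizon_shift: bool = True

    def __post_init__(self):
        if self.M < 1 or self.P < self.M:
            raise ValueError(f"need P >= M >= 1, got P={self.P}, M={self.M}")
        if self.u_min >= self.u_max:
            raise ValueError("need u_min < u_max")
        for name, w, ln in (("mu", self.mu, self.P), ("lam", self.lam, self.M)):
            arr = np.atleast_1d(np.asarray(w, dtype=float))
            if np.any(arr < 0):
                raise ValueError(f"{name} weights must be nonnegative")
            if arr.size not in (1, ln):
                raise ValueError(f"{name} must be scalar or length {ln}")

    @property
    def mu_vec(self) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(np.asarray(self.mu, float)), (self.P,))

    @property
    def lam_vec(self) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(np.asarray(self.lam, float)), (self.M,))


@dataclass
class ClosedLoopHistory:
    """Time-aligned record of one closed-loop run (all arrays share one length)."""

    Ts: float
    r: np.ndarray
    y: np.ndarray
    u: np.ndarray
    d: np.ndarray
    cost: np.ndarray

    def __post_init__(self):
        n = len(self.r)
        for name in ("y", "u", "d", "cost"):
            if len(getattr(self, name)) != n:
                raise ValueError("all history sequences must share one length")

    def __len__(self) -> int:
        return len(self.r)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.r)) * self.Ts

    def to_frame(self, display: DisplayMapping | None = None) -> pd.DataFrame:
        display = display or DisplayMapping()
        return pd.DataFrame(
            {
                "t_s": self.t,
                "r": self.r,
                "u": self.u,
                "y": self.y,
                "d": self.d,
                "map_mmHg": display.to_mmhg(self.y),
            }
        )

    def to_csv(self, path, display: DisplayMapping | None = None) -> None:
        self.to_frame(display).to_csv(path, index=False, float_format="%.12g")


def extend_reference(reference, n_needed: int) -> np.ndarray:
    """Last-value hold beyond the known window (receding-horizon convention)."""
    r = np.atleast_1d(np.asarray(reference, dtype=float))
    if len(r) == 0:
        raise ValueError("reference must contain at least one sample")
    if len(r) >= n_needed:
        return r
    return np.concatenate([r, np.full(n_needed - len(r), r[-1])])


def _costed_slice(cfg: MPCConfig, delay: int) -> tuple[int, int]:
    """(look-ahead length, first costed index) for the configured horizon."""
    shift = delay if cfg.horizon_shift else 0
    return shift + cfg.P, shift


def predict(
    dmodel: DiscretePatientModel,
    past_y,
    past_u,
    future_moves,
    cfg: MPCConfig,
    bias: float = 0.0,
) -> np.ndarray:
    """Model prediction at the P costed instants for a candidate move sequence.

    ``past_y``/``past_u`` are newest-first (``past_y[0]`` is the current
    output y(t), ``past_u[0]`` the previously applied input u(t-1)).  The
    input is held constant after the M-th move.  This is the plain
    whole-trajectory simulation; the optimized closed-loop path uses the
    equivalent free-response + step-response-matrix form.
    """
    moves = np.atleast_1d(np.asarray(future_moves, dtype=float))
    if len(moves) != cfg.M:
        raise ValueError(f"expected {cfg.M} moves, got {len(moves)}")
    past_y = np.asarray(past_y, dtype=float)
    past_u = np.asarray(past_u, dtype=float)
    n = dmodel.order
    m = len(dmodel.num) - 1
    if len(past_y) < n or len(past_u) < dmodel.delay + (n - m) + m:
        raise ValueError("insufficient history for the model order and delay")
    u_prev = past_u[0] if len(past_u) else 0.0
    n_ahead, first = _costed_slice(cfg, dmodel.delay)
    # cumulative rates: u(t) = u_prev + moves[0], ..., held after the M-th move
    cum = u_prev + np.cumsum(moves)
    idx = np.minimum(np.arange(1, n_ahead + 1), cfg.M - 1)
    u_future = cum[idx]  # u(t+1), u(t+2), ...
    # local clock starts at t+1: y(t) becomes the newest past output and the
    # first candidate rate u(t) the newest past input
    hist = InitialHistory(
        past_y=past_y, past_u=np.concatenate([[cum[0]], past_u])
    )
    y = simulate(dmodel, u_future, history=hist)
    return y[first : first + cfg.P] + bias


def cost(predicted, desired, future_moves, cfg: MPCConfig) -> float:
    """Quadratic tracking + move-suppression cost of one candidate sequence."""
    predicted = np.asarray(predicted, dtype=float)
    desired = np.asarray(desired, dtype=float)
    moves = np.atleast_1d(np.asarray(future_moves, dtype=float))
    if predicted.shape != (cfg.P,) or desired.shape != (cfg.P,):
        raise ValueError(
            f"predicted/desired must have length P={cfg.P}, got "
            f"{predicted.shape} and {desired.shape}"
        )
    if len(moves) != cfg.M:
        raise ValueError(f"expected {cfg.M} moves, got {len(moves)}")
    err = predicted - desired
    return float(np.sum(cfg.mu_vec * err**2) + np.sum(cfg.lam_vec * moves**2))


def step_response_matrix(dmodel: DiscretePatientModel, cfg: MPCConfig) -> np.ndarray:
    """P x M matrix mapping move increments to costed-output changes.

    Entry (i, j) is the plant step response, relative to the move instant
    t+j, evaluated at the i-th costed instant; superposition makes the
    predicted output affine in the moves, so one matrix product evaluates a
    whole candidate population.
    """
    delay_free = DiscretePatientModel(
        num=dmodel.num, den=dmodel.den, delay=0, Ts=dmodel.Ts
    )
    # s[q] = delay-free unit step response q samples after the step is applied
    # (s[0] = 0 for any strictly proper plant)
    s = simulate(delay_free, np.ones(cfg.P + 1))
    G = np.zeros((cfg.P, cfg.M))
    shift = dmodel.delay if cfg.horizon_shift else 0
    for i in range(1, cfg.P + 1):
        for j in range(cfg.M):
            q = shift + i - j - dmodel.delay
            if q >= 0:
                G[i - 1, j] = s[q]
    return G


def move_bounds(cfg: MPCConfig, u_prev: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene move bounds implied by the input limits from the current rate."""
    lo = np.full(cfg.M, cfg.u_min - u_prev)
    hi = np.full(cfg.M, cfg.u_max - u_prev)
    return lo, hi


@dataclass
class ControllerState:
    """Internal controller memory: model replica, last applied input, output bias."""

    model: PlantSimulator
    u_prev: float = 0.0
    bias: float = 0.0


@dataclass
class StepResult:
    u: float
    moves: np.ndarray
    cost: float
    zero_move_cost: float
    clipped: bool
    trace: np.ndarray


def make_objective(
    dmodel: DiscretePatientModel,
    state: ControllerState,
    desired: np.ndarray,
    cfg: MPCConfig,
    G: np.ndarray | None = None,
    free: np.ndarray | None = None,
):
    """Batch objective over candidate move sequences for the current step.

    Candidate cumulative rates are clipped to the pump limits before costing,
    so every evaluated chromosome corresponds to a feasible input trajectory.
    """
    if G is None:
        G = step_response_matrix(dmodel, cfg)
    if free is None:
        # the controller model's clock is one step behind the costed window
        # (its newest past output is y(t-1)), so look one sample further ahead
        n_ahead, first = _costed_slice(cfg, dmodel.delay)
        yfree = simulate(
            dmodel,
            np.full(n_ahead + 1, state.u_prev),
            history=state.model.history(),
        )
        free = yfree[first + 1 : first + 1 + cfg.P]
    free_b = free + state.bias
    mu, lam = cfg.mu_vec, cfg.lam_vec
    u_prev = state.u_prev

    def objective(pop: np.ndarray) -> np.ndarray:
        pop = np.atleast_2d(np.asarray(pop, dtype=float))
        U = np.clip(u_prev + np.cumsum(pop, axis=1), cfg.u_min, cfg.u_max)
        du = np.diff(np.concatenate([np.full((len(U), 1), u_prev), U], axis=1), axis=1)
        pred = free_b + du @ G.T
        err = pred - desired
        return (mu * err**2).sum(axis=1) + (lam * du**2).sum(axis=1)

    return objective


def control_step(
    dmodel: DiscretePatientModel,
    state: ControllerState,
    reference_window,
    cfg: MPCConfig,
    optimizer,
    rng: np.random.Generator | None = None,
) -> StepResult:
    """One receding-horizon decision: optimize M moves, return the first.

    ``reference_window`` must cover the P costed instants.  ``optimizer`` is
    any callable ``(objective, bounds, rng, seeds) -> OptResult``; the
    zero-move chromosome is always seeded so the result never does worse than
    holding the current rate.
    """
    desired = np.asarray(reference_window, dtype=float)
    if desired.shape != (cfg.P,):
        raise ValueError(f"reference window must have length P={cfg.P}")
    objective = make_objective(dmodel, state, desired, cfg)
    bounds = move_bounds(cfg, state.u_prev)
    seeds = np.zeros((1, cfg.M))
    res = optimizer(objective, bounds, rng=rng, seeds=seeds)
    moves = np.atleast_1d(np.asarray(res.best_x, dtype=float))
    if moves.shape != (cfg.M,):
        raise ValueError(
            f"optimizer returned a chromosome of length {moves.size}, "
            f"expected M={cfg.M}"
        )
    u_raw = state.u_prev + moves[0]
    u = float(np.clip(u_raw, cfg.u_min, cfg.u_max))
    zero_cost = float(objective(np.zeros((1, cfg.M)))[0])
    return StepResult(
        u=u,
        moves=moves,
        cost=float(res.best_cost),
        zero_move_cost=zero_cost,
        clipped=bool(u != u_raw),
        trace=np.asarray(res.trace, dtype=float),
    )


def run_closed_loop(
    dmodel: DiscretePatientModel,
    reference,
    disturbance,
    cfg: MPCConfig,
    optimizer,
    n_samples: int,
    seed: int | None = 0,
    u_init: float = 0.0,
) -> ClosedLoopHistory:
    """Execute the full receding-horizon loop for ``n_samples`` steps.

    Per step: measure the (possibly disturbed) output, update the bias
    estimate, optimize the move sequence, apply the first move clipped to the
    pump limits, advance the plant.  Deterministic given ``seed`` (one random
    stream feeds the optimizer across steps).
    """
    n_ahead, first = _costed_slice(cfg, dmodel.delay)
    ref = extend_reference(reference, n_samples + n_ahead + 1)
    if disturbance is None:
        dist = np.zeros(n_samples)
    else:
        dist = np.asarray(disturbance, dtype=float)
        if len(dist) < n_samples:
            raise ValueError("disturbance shorter than the simulation window")
    rng = np.random.default_rng(seed)
    plant = PlantSimulator(dmodel)
    state = ControllerState(model=PlantSimulator(dmodel), u_prev=u_init)

    y_out = np.empty(n_samples)
    u_out = np.empty(n_samples)
    j_out = np.empty(n_samples)
    for t in range(n_samples):
        y_meas = plant.output() + dist[t]
        state.bias = y_meas - state.model.output()
        window = ref[t + first + 1 : t + first + 1 + cfg.P]
        res = control_step(dmodel, state, window, cfg, optimizer, rng=rng)
        assert res.cost <= res.zero_move_cost + 1e-9
        u = res.u
        plant.advance(u)
        state.model.advance(u)
        state.u_prev = u
        y_out[t] = y_meas
        u_out[t] = u
        j_out[t] = res.cost
    return ClosedLoopHistory(
        Ts=dmodel.Ts,
        r=ref[:n_samples].copy(),
        y=y_out,
        u=u_out,
        d=dist[:n_samples].copy(),
        cost=j_out,
    )
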