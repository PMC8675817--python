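"""Scenario definitions and the experiment suite.

One :class:`Scenario` bundles everything a run needs: the patient model, the
controller (``ga_mpc``, ``pso_mpc``, ``grid_mpc`` or ``pid``), the step
reference, an optional sinusoidal disturbance, the window length and the
seed.  On top of single runs the module provides the three studies of the
tool: the prediction-horizon sweep, the disturbance-rejection comparison and
the four-controller ranking.

Conventions
-----------
* The reference is a normalized step (1 = full swing from the initial to the
  target pressure); the display mapping renders mmHg.
* Disturbance amplitudes are given in display units (mmHg) and divided by
  the display span to act on the normalized measured output; default period
  100 s, entry at t = 0.
* Reported indices are delay-aligned (see :mod:`mapmpc.metrics`); the
  unaligned from-t=0 variant is included in every JSON report.
* Sweeps reuse one seed per run so that identical settings reproduce
  identical rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline_controllers import (
    PSOConfig,
    pso_optimize,
    run_pid_loop,
    ziegler_nichols_tune,
)
from .ga_optimizer import GAConfig, ga_optimize, grid_oracle
from .metrics import MetricsReport, compute_metrics
from .mpc_controller import (
    ClosedLoopHistory,
    ControllerState,
    MPCConfig,
    control_step,
    run_closed_loop,
)
from .patient_model import (
    ContinuousPatientModel,
    DiscretePatientModel,
    DisplayMapping,
    PlantSimulator,
    canonical_model,
    discretize_zoh,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "SinusoidDisturbance",
    "StepReference",
    "compare_controllers",
    "disturbance_test",
    "ga_convergence_demo",
    "make_disturbance",
    "make_optimizer",
    "make_reference",
    "run_scenario",
    "sweep_horizon",
]

CONTROLLERS = ("ga_mpc", "pso_mpc", "grid_mpc", "pid")


@dataclass(frozen=True)
class StepReference:
    amplitude: float = 1.0
    start: int = 0


@dataclass(frozen=True)
class SinusoidDisturbance:
    """Output-additive sinusoid; amplitude in display units (mmHg)."""

    amplitude_mmhg: float = 10.0
    period_s: float = 100.0
    start: int = 0
    phase: float = 0.0

    def __post_init__(self):
        if self.amplitude_mmhg < 0:
            raise ValueError("disturbance amplitude must be nonnegative")
        if self.period_s <= 0:
            raise ValueError("disturbance period must be positive")


@dataclass(frozen=True)
class Scenario:
    name: str = "tracking"
    controller: str = "ga_mpc"
    mpc: MPCConfig = field(default_factory=MPCConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    grid_points: int = 101
    reference: StepReference = field(default_factory=StepReference)
    disturbance: SinusoidDisturbance | None = None
    window: int = 200
    seed: int = 0
    display: DisplayMapping = field(default_factory=DisplayMapping)
    Ts: float = 1.0

    def __post_init__(self):
        if self.controller not in CONTROLLERS:
            raise ValueError(
                f"unknown controller {self.controller!r}; pick one of {CONTROLLERS}"
            )
        if self.window < 1:
            raise ValueError("window must contain at least one sample")


@dataclass
class ScenarioResult:
    scenario: Scenario
    history: ClosedLoopHistory
    metrics: MetricsReport  # delay-aligned
    metrics_from_t0: MetricsReport

    def report(self) -> dict:
        return {
            "scenario": self.scenario.name,
            "controller": self.scenario.controller,
            "seed": self.scenario.seed,
            "window": self.scenario.window,
            "metrics_delay_aligned": self.metrics.to_dict(),
            "metrics_from_t0": self.metrics_from_t0.to_dict(),
        }


def make_reference(spec: StepReference, n: int) -> np.ndarray:
    r = np.zeros(n)
    r[spec.start :] = spec.amplitude
    return r


def make_disturbance(
    spec: SinusoidDisturbance | None, n: int, Ts: float, display: DisplayMapping
) -> np.ndarray:
    """Sinusoid in mmHg mapped to normalized output units."""
    if spec is None:
        return np.zeros(n)
    amp = display.normalize_amplitude(spec.amplitude_mmhg)
    t = np.arange(n) * Ts
    d = amp * np.sin(2.0 * np.pi * t / spec.period_s + spec.phase)
    d[: spec.start] = 0.0
    return d


def make_optimizer(scenario: Scenario):
    """Move-sequence optimizer callable for the scenario's MPC variant."""
    if scenario.controller == "ga_mpc":
        return lambda obj, bounds, rng=None, seeds=None: ga_optimize(
            obj, bounds, scenario.ga, rng=rng, seeds=seeds
        )
    if scenario.controller == "pso_mpc":
        return lambda obj, bounds, rng=None, seeds=None: pso_optimize(
            obj, bounds, scenario.pso, rng=rng, seeds=seeds
        )
    if scenario.controller == "grid_mpc":
        return lambda obj, bounds, rng=None, seeds=None: grid_oracle(
            obj, bounds, scenario.grid_points
        )
    raise ValueError(f"no move-sequence optimizer for {scenario.controller!r}")


def default_plant(Ts: float = 1.0) -> DiscretePatientModel:
    return discretize_zoh(canonical_model(), Ts)


def run_scenario(
    scenario: Scenario,
    plant: DiscretePatientModel | None = None,
    out_dir=None,
) -> ScenarioResult:
    """End-to-end execution: build signals, run the loop, score, optionally write.

    Artifacts written under ``out_dir``: ``<name>_<controller>.csv`` (time
    series incl. the mmHg rendering) and ``<name>_<controller>.json``
    (metrics in both error conventions).
    """
    dmodel = plant if plant is not None else default_plant(scenario.Ts)
    n = scenario.window
    ref = make_reference(scenario.reference, n)
    dist = make_disturbance(scenario.disturbance, n, dmodel.Ts, scenario.display)
    if scenario.controller == "pid":
        gains = ziegler_nichols_tune(dmodel)
        history = run_pid_loop(
            dmodel, ref, dist, gains, n,
            u_min=scenario.mpc.u_min, u_max=scenario.mpc.u_max,
        )
    else:
        history = run_closed_loop(
            dmodel, ref, dist, scenario.mpc, make_optimizer(scenario),
            n, seed=scenario.seed,
        )
    result = ScenarioResult(
        scenario=scenario,
        history=history,
        metrics=compute_metrics(history, delay_align=dmodel.delay),
        metrics_from_t0=compute_metrics(history),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"{scenario.name}_{scenario.controller}"
        history.to_csv(out / f"{stem}.csv", display=scenario.display)
        with open(out / f"{stem}.json", "w") as fh:
            json.dump(result.report(), fh, indent=2)
    return result


def sweep_horizon(
    p_values,
    base: Scenario,
    plant: DiscretePatientModel | None = None,
) -> pd.DataFrame:
    """One run per prediction horizon, same seed, indices in table layout."""
    rows = []
    for P in p_values:
        if P < base.mpc.M:
            raise ValueError(f"P={P} smaller than the control horizon M={base.mpc.M}")
        sc = replace(base, name=f"{base.name}_P{P}", mpc=replace(base.mpc, P=int(P)))
        res = run_scenario(sc, plant=plant)
        m = res.metrics
        rows.append({"P": int(P), "ISE": m.ISE, "MSE": m.MSE, "IAE": m.IAE})
    return pd.DataFrame(rows)


def disturbance_test(
    base: Scenario,
    disturbance: SinusoidDisturbance | None = None,
    plant: DiscretePatientModel | None = None,
) -> pd.DataFrame:
    """Indices with and without the sinusoidal disturbance, same seed."""
    disturbance = disturbance or SinusoidDisturbance()
    rows = []
    for label, dist in (("without", None), ("with", disturbance)):
        sc = replace(base, name=f"{base.name}_{label}", disturbance=dist)
        m = run_scenario(sc, plant=plant).metrics
        rows.append(
            {"disturbance": label, "ISE": m.ISE, "MSE": m.MSE, "IAE": m.IAE}
        )
    return pd.DataFrame(rows)


def compare_controllers(
    base: Scenario,
    controllers=CONTROLLERS,
    plant: DiscretePatientModel | None = None,
) -> pd.DataFrame:
    """IAE/ISE/MSE per controller in the canonical tracking scenario."""
    rows = []
    for ctrl in controllers:
        sc = replace(base, controller=ctrl)
        m = run_scenario(sc, plant=plant).metrics
        rows.append({"controller": ctrl, "IAE": m.IAE, "ISE": m.ISE, "MSE": m.MSE})
    return pd.DataFrame(rows)


def ga_convergence_demo(
    scenario: Scenario | None = None,
    plant: DiscretePatientModel | None = None,
) -> np.ndarray:
    """Best-cost-per-generation trace of the GA on the first control decision."""
    scenario = scenario or Scenario()
    dmodel = plant if plant is not None else default_plant(scenario.Ts)
    state = ControllerState(model=PlantSimulator(dmodel))
    shift = dmodel.delay if scenario.mpc.horizon_shift else 0
    n_need = scenario.window + shift + scenario.mpc.P + 1
    ref = make_reference(scenario.reference, n_need)
    window = ref[shift + 1 : shift + 1 + scenario.mpc.P]
    rng = np.random.default_rng(scenario.seed)
    res = control_step(
        dmodel, state, window, scenario.mpc, make_optimizer(scenario), rng=rng
    )
    return res.trace
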