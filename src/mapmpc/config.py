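"""YAML configuration loading for the command-line interface.

Top-level keys mirror the library dataclasses::

    patient:     {gain, time_constants, alpha, dead_time_s}   # omit => canonical
    sampling_time_s: 1.0
    controller:  ga_mpc | pso_mpc | grid_mpc | pid
    mpc:         {P, M, mu, lambda, u_min, u_max, horizon_shift, window_samples}
    ga:          {population, generations, p_crossover, p_mutation, elite, seed}
    pso:         {swarm, iterations, inertia, cognitive, social}
    reference:   {amplitude, start}
    disturbance: {amplitude_mmhg, period_s, start}
    display:     {map_initial, map_target}
    muscle:      {J, B, k}
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .baseline_controllers import PSOConfig
from .experiments import Scenario, SinusoidDisturbance, StepReference
from .ga_optimizer import GAConfig
from .heart_mechanics import MuscleModel
from .mpc_controller import MPCConfig
from .patient_model import DisplayMapping, continuous_from_config

__all__ = ["load_config", "muscle_from_config", "scenario_from_config"]


def load_config(path) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(cfg)}")
    return cfg


def _mpc_from(cfg: dict) -> tuple[MPCConfig, int]:
    window = int(cfg.get("window_samples", 200))
    kwargs = {
        k: cfg[k]
        for k in ("P", "M", "mu", "u_min", "u_max", "horizon_shift")
        if k in cfg
    }
    if "lambda" in cfg:
        kwargs["lam"] = cfg["lambda"]
    return MPCConfig(**kwargs), window


def scenario_from_config(cfg: dict, seed: int | None = None) -> Scenario:
    """Build a Scenario from a parsed configuration mapping.

    ``seed`` (e.g. from the CLI) overrides any seed in the file.
    """
    mpc, window = _mpc_from(cfg.get("mpc", {}))
    sc = Scenario(
        name=cfg.get("name", "tracking"),
        controller=cfg.get("controller", "ga_mpc"),
        mpc=mpc,
        ga=GAConfig(**cfg.get("ga", {})),
        pso=PSOConfig(**cfg.get("pso", {})),
        reference=StepReference(**cfg.get("reference", {})),
        disturbance=(
            SinusoidDisturbance(**cfg["disturbance"])
            if cfg.get("disturbance")
            else None
        ),
        window=window,
        display=DisplayMapping(**cfg.get("display", {})),
        Ts=float(cfg.get("sampling_time_s", 1.0)),
        seed=int(cfg.get("seed", 0)),
    )
    if seed is not None:
        sc = replace(sc, seed=int(seed))
    return sc


def muscle_from_config(cfg: dict) -> MuscleModel:
    return MuscleModel(**cfg.get("muscle", {}))


def patient_from_config(cfg: dict):
    return continuous_from_config(cfg.get("patient", {}))
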