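"""Real-coded genetic algorithm over bounded control-move sequences.

The optimizer minimizes an objective over a box in R^M (here: the M drug
infusion-rate increments of one predictive-control step).  The algorithm is
the classic generational scheme: tournament selection (size 2), whole
arithmetic (blend) crossover, per-gene additive Gaussian mutation clipped to
the bounds, and elitism.  A brute-force regular-grid minimizer is provided as
an independent verification oracle.

Objectives are evaluated in batch: ``objective(pop)`` receives an
``(n_candidates, M)`` array and returns ``n_candidates`` costs.  Use
:func:`batched` to lift a scalar chromosome -> cost function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAConfig",
    "OptResult",
    "batched",
    "convergence_trace",
    "ga_optimize",
    "grid_oracle",
]


@dataclass(frozen=True)
class GAConfig:
    """GA hyper-parameters.

    Defaults are the study settings: population 100, 10 generations,
    crossover probability 0.7, per-gene mutation probability 0.005, one elite,
    full generational replacement (insertion rate 1).  ``mutation_sigma_frac``
    sets the mutation step as a fraction of each gene's bound width.
    """

    population: int = 100
    generations: int = 10
    p_crossover: float = 0.7
    p_mutation: float = 0.005
    elite: int = 1
    mutation_sigma_frac: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if self.generations < 1:
            raise ValueError("at least one generation is required")
        for name in ("p_crossover", "p_mutation"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not (0 <= self.elite < self.population):
            raise ValueError("elite count must be in [0, population)")


@dataclass
class OptResult:
    """Best chromosome found, its cost, and the per-generation best-cost trace."""

    best_x: np.ndarray
    best_cost: float
    trace: np.ndarray
    n_evaluations: int = 0


def batched(scalar_objective):
    """Lift a chromosome -> scalar objective to the batch calling convention."""

    def _f(pop: np.ndarray) -> np.ndarray:
        return np.array([scalar_objective(x) for x in np.atleast_2d(pop)])

    return _f


def _check_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = (np.atleast_1d(np.asarray(b, dtype=float)) for b in bounds)
    if lo.shape != hi.shape:
        raise ValueError("lower and upper bounds must have the same shape")
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    if np.any(lo >= hi):
        raise ValueError(f"need lower < upper bounds, got lo={lo}, hi={hi}")
    return lo, hi


def ga_optimize(
    objective,
    bounds,
    cfg: GAConfig | None = None,
    rng: np.random.Generator | None = None,
    seeds=None,
) -> OptResult:
    """Minimize ``objective`` over the box ``bounds = (lo, hi)``.

    ``seeds`` are candidate chromosomes injected into generation 0 (e.g. the
    zero-move chromosome, which guarantees the result never degrades the
    do-nothing cost).  Fully deterministic given ``rng`` (or ``cfg.seed``).
    """
    cfg = cfg or GAConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = _check_bounds(bounds)
    m = len(lo)
    npop = cfg.population

    pop = rng.uniform(lo, hi, size=(npop, m))
    if seeds is not None:
        seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
        k = min(len(seeds), npop)
        pop[:k] = np.clip(seeds[:k], lo, hi)

    sigma = cfg.mutation_sigma_frac * (hi - lo)
    best_x = None
    best_cost = np.inf
    trace = np.empty(cfg.generations)
    n_eval = 0

    for gen in range(cfg.generations):
        cost = np.asarray(objective(pop), dtype=float)
        n_eval += npop
        if cost.shape != (npop,):
            raise ValueError(
                f"objective returned shape {cost.shape}, expected ({npop},)"
            )
        if not np.all(np.isfinite(cost)):
            bad = pop[~np.isfinite(cost)][0]
            raise ValueError(f"objective returned a non-finite value at {bad}")
        order = np.argsort(cost, kind="stable")
        if cost[order[0]] < best_cost:
            best_cost = float(cost[order[0]])
            best_x = pop[order[0]].copy()
        trace[gen] = cost[order[0]]
        if gen == cfg.generations - 1:
            break

        # tournament selection, size 2
        i1 = rng.integers(0, npop, npop)
        i2 = rng.integers(0, npop, npop)
        winners = np.where(cost[i1] <= cost[i2], i1, i2)
        parents = pop[winners]

        # whole arithmetic crossover on consecutive pairs
        children = parents.copy()
        do_cx = rng.random(npop // 2) < cfg.p_crossover
        gamma = rng.random(npop // 2)
        for p_idx in range(npop // 2):
            if do_cx[p_idx]:
                a, b = parents[2 * p_idx], parents[2 * p_idx + 1]
                g = gamma[p_idx]
                children[2 * p_idx] = g * a + (1 - g) * b
                children[2 * p_idx + 1] = (1 - g) * a + g * b

        # per-gene Gaussian mutation, clipped back into the box
        mask = rng.random(children.shape) < cfg.p_mutation
        noise = rng.normal(0.0, 1.0, size=children.shape) * sigma
        children = np.clip(children + mask * noise, lo, hi)

        # elitism: the current best individuals survive unchanged
        if cfg.elite > 0:
            children[: cfg.elite] = pop[order[: cfg.elite]]
        pop = children
        assert np.all(pop >= lo - 1e-12) and np.all(pop <= hi + 1e-12)

    return OptResult(
        best_x=best_x, best_cost=best_cost, trace=trace, n_evaluations=n_eval
    )


def convergence_trace(result: OptResult) -> np.ndarray:
    """Per-generation best cost (monotone non-increasing whenever elite >= 1)."""
    return result.trace


def grid_oracle(objective, bounds, points_per_gene: int = 101) -> OptResult:
    """Exhaustive minimization on a regular grid; ties break toward the
    lexicographically smallest chromosome.

    Intended as a deterministic verification oracle (and as the optimizer of
    the plain-MPC baseline); cost grows as ``points_per_gene ** n_genes``.
    """
    lo, hi = _check_bounds(bounds)
    axes = [np.linspace(lo[i], hi[i], points_per_gene) for i in range(len(lo))]
    # itertools.product order = first gene slowest => row order is lexicographic,
    # and argmin returns the first minimum
    grid = np.array(list(itertools.product(*axes)))
    cost = np.asarray(objective(grid), dtype=float)
    i = int(np.argmin(cost))
    return OptResult(
        best_x=grid[i].copy(),
        best_cost=float(cost[i]),
        trace=np.array([float(cost[i])]),
        n_evaluations=len(grid),
    )
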