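"""Real-coded genetic algorithm for surrogate optimization and network seeding.

The GA follows the classic MATLAB-style operator suite: rank-scaled
fitness (scaled value ∝ 1/√rank), stochastic-uniform (SUS) parent
selection, elitism, intermediate crossover and shrinking-scale Gaussian
mutation (uniform-within-bounds resampling available by config), with
optional forward ring migration between subpopulations.
Only box constraints arise in this problem, so feasibility is maintained
by bound-respecting operators and clipping rather than a nonlinear
constraint handler.

Two applications: seeding the neural-network weights/biases before
gradient refinement, and locating optimal extraction conditions by
minimising the negative composite desirability of the surrogate's
predictions over the factor box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .ann import (
    AffineScaler,
    Network,
    TrainConfig,
    DataSplit,
    _forward_resid_jac,
    n_params,
    train,
    unflatten_params,
)
from .dataset import ResponseGroup, ResponseTable
from .design import FactorSpace
from .rsm import DesirabilityGoal, OptimizationResult, composite_desirability

__all__ = [
    "GAConfig",
    "GAResult",
    "NonFiniteObjectiveError",
    "ga_minimize",
    "ga_seed_network",
    "optimize_conditions",
]


class NonFiniteObjectiveError(RuntimeError):
    """Raised when the objective returns a non-finite value at an in-bounds point."""

    def __init__(self, point: np.ndarray, value: float):
        self.point = np.asarray(point)
        self.value = value
        super().__init__(f"objective returned {value!r} at {self.point.tolist()}")


@dataclass(frozen=True)
class GAConfig:
    """Operator settings (MATLAB-toolbox-style defaults)."""

    population_size: int = 50
    elite_fraction: float = 0.05
    crossover_fraction: float = 0.8
    mutation: str = "gaussian"  # "gaussian" (shrinking scale) or "uniform"
    mutation_rate: float = 0.1  # per-gene resample rate for "uniform"
    mutation_scale: float = 1.0  # initial Gaussian sd in units of the box range
    mutation_shrink: float = 1.0  # linear decay of the Gaussian sd over generations
    migration_fraction: float = 0.2
    migration_interval: int = 20
    n_subpopulations: int = 1
    max_generations: int = 100
    stall_generations: int | None = None  # None: run the full generation budget
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValueError("crossover_fraction must lie in [0, 1]")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be < population_size")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")

    @property
    def elite_count(self) -> int:
        return math.ceil(self.elite_fraction * self.population_size)


@dataclass(frozen=True)
class GAResult:
    """Best point found, its objective value and the per-generation history."""

    best_x: np.ndarray
    best_fitness: float
    history: tuple[float, ...]
    generations_run: int
    seed: int


def _rank_scaled(fitness: np.ndarray) -> np.ndarray:
    """Scaled selection weights ∝ 1/√rank (rank 1 = best, i.e. lowest objective)."""
    order = np.argsort(fitness, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(fitness) + 1)
    w = 1.0 / np.sqrt(ranks)
    return w / w.sum()


def _sus(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic uniform sampling of n parents from the selection weights."""
    positions = (rng.uniform(0, 1.0 / n) + np.arange(n) / n)
    cum = np.cumsum(weights)
    return np.searchsorted(cum, positions)


def ga_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: GAConfig | None = None,
) -> GAResult:
    """Minimise a scalar objective over a box with the generational GA.

    Per generation and subpopulation: elites pass unchanged,
    round(crossover_fraction · (pop − elite)) offspring come from
    intermediate crossover of SUS-selected parents
    (child = p1 + u·(p2 − p1), u ~ U(0, 1) per gene), the remainder from
    mutation of selected parents — by default Gaussian perturbation whose
    scale shrinks linearly over the generations (coarse exploration early,
    fine refinement late), or per-gene uniform resampling within bounds
    with ``mutation="uniform"``.  All
    offspring are clipped to the box.  Terminates at ``max_generations``
    or after ``stall_generations`` without improvement of the best value.
    """
    config = config or GAConfig()
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("bounds must define a nonempty box")
    ndim = len(bounds)
    rng = np.random.default_rng(config.seed)

    def evaluate(pop: np.ndarray) -> np.ndarray:
        vals = np.empty(len(pop))
        for i, x in enumerate(pop):
            v = float(objective(x))
            if not np.isfinite(v):
                raise NonFiniteObjectiveError(x, v)
            vals[i] = v
        return vals

    nsub = config.n_subpopulations
    base = config.population_size // nsub
    sizes = [base + (1 if i < config.population_size % nsub else 0) for i in range(nsub)]
    pops = [rng.uniform(lo, hi, size=(s, ndim)) for s in sizes]
    fits = [evaluate(p) for p in pops]

    best_x = None
    best_f = np.inf
    history: list[float] = []
    stall = 0
    gen = 0

    for gen in range(1, config.max_generations + 1):
        for s in range(nsub):
            pop, fit = pops[s], fits[s]
            npop = len(pop)
            n_elite = min(config.elite_count, npop - 1)
            order = np.argsort(fit, kind="stable")
            elites = pop[order[:n_elite]].copy()

            n_off = npop - n_elite
            n_xover = int(round(config.crossover_fraction * n_off))
            n_mut = n_off - n_xover
            weights = _rank_scaled(fit)
            parents = pop[_sus(weights, 2 * n_xover + n_mut, rng)]

            children = []
            for k in range(n_xover):
                p1, p2 = parents[2 * k], parents[2 * k + 1]
                u = rng.uniform(0.0, 1.0, size=ndim)
                children.append(p1 + u * (p2 - p1))
            if config.mutation == "gaussian":
                # coarse-to-fine: sd decays linearly from mutation_scale
                # of the box range toward (1 - shrink) of it
                frac = 1.0 - config.mutation_shrink * gen / config.max_generations
                sd = config.mutation_scale * max(frac, 0.0) * (hi - lo)
            for k in range(n_mut):
                p = parents[2 * n_xover + k].copy()
                if config.mutation == "gaussian":
                    p = p + rng.normal(0.0, 1.0, size=ndim) * sd
                elif config.mutation == "uniform":
                    mask = rng.uniform(size=ndim) < config.mutation_rate
                    p[mask] = rng.uniform(lo[mask], hi[mask])
                else:
                    raise ValueError(f"unknown mutation {config.mutation!r}")
                children.append(p)
            new_pop = np.vstack([elites] + children) if children else elites
            new_pop = np.clip(new_pop, lo, hi)
            new_fit = np.concatenate([fit[order[:n_elite]], evaluate(new_pop[n_elite:])])
            pops[s], fits[s] = new_pop, new_fit

        if nsub > 1 and gen % config.migration_interval == 0:
            n_mig = max(1, int(round(config.migration_fraction * min(sizes))))
            movers = []
            for s in range(nsub):
                order = np.argsort(fits[s], kind="stable")
                movers.append((pops[s][order[:n_mig]].copy(), fits[s][order[:n_mig]].copy()))
            for s in range(nsub):  # forward ring: s -> s+1, replacing the worst
                dst = (s + 1) % nsub
                order = np.argsort(fits[dst], kind="stable")
                worst = order[::-1][:n_mig]
                pops[dst][worst] = movers[s][0]
                fits[dst][worst] = movers[s][1]

        gen_best = min(float(f.min()) for f in fits)
        if gen_best < best_f:
            i_sub = int(np.argmin([f.min() for f in fits]))
            i = int(np.argmin(fits[i_sub]))
            best_f = gen_best
            best_x = pops[i_sub][i].copy()
            stall = 0
        else:
            stall += 1
        history.append(best_f)
        stall_limit = config.stall_generations or config.max_generations
        if stall >= stall_limit:
            break

    return GAResult(
        best_x=best_x,
        best_fitness=best_f,
        history=tuple(history),
        generations_run=gen,
        seed=config.seed,
    )


def ga_seed_network(
    table: ResponseTable,
    group: ResponseGroup,
    ga_config: GAConfig | None = None,
    train_config: TrainConfig | None = None,
    split: DataSplit | None = None,
    weight_bound: float = 2.0,
) -> tuple[Network, "GAResult"]:
    """GA-optimise the MLP weights/thresholds, then refine by gradient training.

    The chromosome is the flattened (hidden weights, hidden biases,
    output weights, output biases) vector, each gene bounded in
    [−weight_bound, weight_bound]; fitness is the combined training +
    validation MSE of the decoded network.  The best individual seeds
    :func:`poriaopt.ann.train` and the refined network is returned.
    """
    from .ann import split_runs

    ga_config = ga_config or GAConfig()
    train_config = train_config or TrainConfig()
    split = split or split_runs(table.n_runs, seed=train_config.seed)

    idx_resp = [table.response_index(n) for n in group.members]
    X = table.design.actual_matrix
    Y = table.means[:, idx_resp]
    layout = (X.shape[1], 10, len(idx_resp))
    in_sc = AffineScaler.fit(X[split.train_idx])
    out_sc = AffineScaler.fit(Y[split.train_idx])
    Z, T = in_sc.apply(X), out_sc.apply(Y)
    fit_idx = np.concatenate([split.train_idx, split.val_idx])
    Zf, Tf = Z[fit_idx], T[fit_idx]

    def fitness(theta: np.ndarray) -> float:
        R, _ = _forward_resid_jac(theta, layout, Zf, Tf, need_jac=False)
        return float(R @ R) / R.size

    P = n_params(layout)
    result = ga_minimize(fitness, [(-weight_bound, weight_bound)] * P, ga_config)
    W1, b1, W2, b2 = unflatten_params(result.best_x, layout)
    seeded = Network(layout, W1, b1, W2, b2, in_sc, out_sc, tuple(group.members))
    refined, _ = train(seeded, table, group, split, train_config)
    return refined, result


def optimize_conditions(
    predictor: Callable[[np.ndarray], np.ndarray],
    goals: list[DesirabilityGoal],
    factor_space: FactorSpace,
    ga_config: GAConfig | None = None,
    predictor_names: Sequence[str] | None = None,
) -> OptimizationResult:
    """GA-maximise composite desirability of predicted responses over the box.

    ``predictor`` maps a 3-vector of actual factor settings to the
    predicted responses, in ``predictor_names`` order (defaults to goal
    order) — a trained network's ``predict`` or stacked RSM fits alike.
    """
    if not goals:
        raise ValueError("at least one goal is required")
    ga_config = ga_config or GAConfig()
    names = list(predictor_names) if predictor_names is not None else [
        g.response_name for g in goals
    ]
    col = {n: i for i, n in enumerate(names)}
    sel = [col[g.response_name] for g in goals]

    def objective(x: np.ndarray) -> float:
        vals = np.asarray(predictor(np.asarray(x, float)), dtype=float).ravel()
        return -float(composite_desirability(vals[sel][None, :], goals))

    bounds = list(zip(factor_space.low, factor_space.high))
    result = ga_minimize(objective, bounds, ga_config)
    vals = np.asarray(predictor(result.best_x), dtype=float).ravel()
    preds = {g.response_name: float(vals[col[g.response_name]]) for g in goals}
    return OptimizationResult(
        x_actual=result.best_x,
        predicted=preds,
        composite_desirability=float(-result.best_fitness),
        method="ga",
    )
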