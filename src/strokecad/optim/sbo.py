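"""Satin bowerbird optimization (SBO).

A population of bowers (candidate vectors) evolves by elite-guided
attraction, Gaussian mutation and elitist generational merging:

    cost_i = 1/(1 + f_i) if f_i >= 0 else 1 + |f_i|
    Prob_i = cost_i / sum_k cost_k
    x_ik <- x_ik + beta_k * ((x_jk + x_elite,k)/2 - x_ik),
            beta_k = alpha / (1 + Prob_j),   j ~ roulette(Prob)
    x_ik <- x_ik + sigma * N(0,1)  with prob. mutation_prob,
            sigma = Z * (VarMax - VarMin)

Each cycle evaluates the modified population, merges it with the old one,
sorts by fitness and truncates back to the population size, so the best
bower (the elite) can never be lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InputError
from .common import Bounds, ObjectiveFn, RunHistory, evaluate_objective


@dataclass
class SBOConfig:
    n: int = 30
    iterations: int = 500
    seed: int = 0
    alpha: float = 0.94
    z: float = 0.02
    mutation_prob: float = 0.05
    beta_uses_self: bool = False  # use Prob_i instead of the target's Prob_j in beta
    initial_positions: np.ndarray | None = None  # rows injected into the first population

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise InputError("iterations must be >= 0")
        if self.n < 2:
            raise InputError("population size must be >= 2")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise InputError("mutation_prob must lie in [0, 1]")


@dataclass
class BowerPopulation:
    positions: np.ndarray  # (n, d)
    fitness: np.ndarray  # (n,)
    costs: np.ndarray = field(default=None)  # type: ignore[assignment]
    probs: np.ndarray = field(default=None)  # type: ignore[assignment]
    elite: np.ndarray = field(default=None)  # type: ignore[assignment]
    elite_fitness: float = np.inf
    alpha: float = 0.94
    z: float = 0.02
    mutation_prob: float = 0.05

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


def sbo_initialize(n: int, bounds: Bounds, seed: int, **kwargs) -> BowerPopulation:
    """Primary uniform random population within [VarMin, VarMax]."""
    if n < 2:
        raise InputError("population size must be >= 2")
    rng = np.random.default_rng(seed)
    positions = bounds.uniform(n, rng)
    return BowerPopulation(
        positions=positions, fitness=np.full(n, np.inf), **kwargs
    )


def sbo_probabilities(population: BowerPopulation) -> np.ndarray:
    """Selection probabilities from fitness: cost = 1/(1+f) for f >= 0,
    1 + |f| for f < 0; Prob = cost / sum(cost).  Costs are strictly
    positive, so the output is always a valid probability vector."""
    f = np.asarray(population.fitness, dtype=float)
    costs = np.where(f >= 0, 1.0 / (1.0 + f), 1.0 + np.abs(f))
    probs = costs / costs.sum()
    population.costs = costs
    population.probs = probs
    return probs


def sbo_update(
    population: BowerPopulation, bounds: Bounds, rng: np.random.Generator,
    beta_uses_self: bool = False,
) -> np.ndarray:
    """Elite-guided attraction step; returns new positions (unevaluated).

    For every individual and every dimension a target bower j is drawn by
    roulette wheel; the step size beta_k = alpha / (1 + Prob_j) shrinks
    toward higher-quality targets (``beta_uses_self`` switches to the
    individual's own probability, a variant left open by the published
    step-size rule).
    """
    if population.probs is None:
        sbo_probabilities(population)
    if population.elite is None:
        raise InputError("elite must be set before sbo_update")
    n, d = population.positions.shape
    probs = population.probs
    new_pos = np.empty_like(population.positions)
    for i in range(n):
        js = rng.choice(n, size=d, p=probs)
        p_ref = probs[i] if beta_uses_self else probs[js]
        beta = population.alpha / (1.0 + p_ref)
        x = population.positions[i]
        target = (population.positions[js, np.arange(d)] + population.elite) / 2.0
        new_pos[i] = x + beta * (target - x)
    return bounds.clamp(new_pos)


def sbo_mutate(
    positions: np.ndarray, bounds: Bounds, rng: np.random.Generator,
    z: float, mutation_prob: float,
) -> np.ndarray:
    """Gaussian mutation: per element, with prob ``mutation_prob``,
    x <- x + sigma*N(0,1) where sigma = z*(VarMax - VarMin); clamped."""
    sigma = z * bounds.range
    mask = rng.random(positions.shape) < mutation_prob
    noise = rng.normal(0.0, 1.0, positions.shape)
    return bounds.clamp(positions + mask * sigma * noise)


def merge_and_truncate(
    old_pos: np.ndarray, old_fit: np.ndarray,
    new_pos: np.ndarray, new_fit: np.ndarray, n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Elitist generational merge: pool both populations, sort by fitness
    ascending (stable), keep the n best."""
    pos = np.vstack([old_pos, new_pos])
    fit = np.concatenate([old_fit, new_fit])
    order = np.argsort(fit, kind="stable")[:n]
    return pos[order], fit[order]


def sbo_run(objective: ObjectiveFn, bounds: Bounds, config: SBOConfig | None = None) -> RunHistory:
    """Run SBO; returns a non-increasing best-fitness trace.

    ``config.initial_positions`` rows replace the first rows of the
    uniform initial population, which lets a caller seed the search with
    a known-good solution (elitism then guarantees the result is never
    worse than that seed).
    """
    cfg = config or SBOConfig()
    rng = np.random.default_rng(cfg.seed)
    pop = sbo_initialize(
        cfg.n, bounds, seed=int(rng.integers(2**31)),
        alpha=cfg.alpha, z=cfg.z, mutation_prob=cfg.mutation_prob,
    )
    if cfg.initial_positions is not None:
        injected = bounds.clamp(np.atleast_2d(np.asarray(cfg.initial_positions, dtype=float)))
        k = min(injected.shape[0], cfg.n)
        pop.positions[:k] = injected[:k]

    history = RunHistory(seed=cfg.seed)
    pop.fitness = np.array([evaluate_objective(objective, x) for x in pop.positions])
    history.evaluations += pop.n
    best = int(np.argmin(pop.fitness))
    pop.elite = pop.positions[best].copy()
    pop.elite_fitness = float(pop.fitness[best])
    history.record(pop.elite_fitness, pop.elite)

    for _ in range(cfg.iterations):
        sbo_probabilities(pop)
        new_pos = sbo_update(pop, bounds, rng, beta_uses_self=cfg.beta_uses_self)
        new_pos = sbo_mutate(new_pos, bounds, rng, cfg.z, cfg.mutation_prob)
        new_fit = np.array([evaluate_objective(objective, x) for x in new_pos])
        history.evaluations += pop.n
        pop.positions, pop.fitness = merge_and_truncate(
            pop.positions, pop.fitness, new_pos, new_fit, cfg.n
        )
        if pop.fitness[0] < pop.elite_fitness:
            pop.elite = pop.positions[0].copy()
            pop.elite_fitness = float(pop.fitness[0])
        history.record(pop.elite_fitness, pop.elite)
    return history
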