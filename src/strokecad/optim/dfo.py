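"""Dragonfly optimization (DFO) and its improved variant (IDFO).

A swarm of candidate positions X with step (velocity) vectors dX evolves
under five behaviors computed from neighbors within a growing radius:

    separation  S_i = -sum_j (X - X_j)
    alignment   A_i = mean_j V_j
    cohesion    C_i = mean_j X_j - X
    food        F_i = X+ - X          (X+ = best position seen so far)
    enemy       E_i = X- + X          (X- = worst of the current iteration)

    dX(t+1) = s*S + a*A + c*C + f*F + e*E + w*dX(t),   X(t+1) = X(t) + dX(t+1)

The enemy term is implemented exactly as published (X- + X); the
``outward`` variant (X- - X) is available via config.  Individuals with
no neighbors take a heavy-tailed Levy-flight move instead.  The improved
variant adds the uniform per-dimension random initialization and an
optional disabled-by-default global-pollination move toward the food
source.  Coefficient schedule (none is published with the update rule):
inertia w anneals linearly 0.9 -> 0.4; s, a, c ~ U[0, 2r_t] with
r_t = max(0, 0.1 - t/(T/2) * 0.1); f ~ U[0, 2]; e = r_t; steps are
clipped to one tenth of the box range per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InputError
from .common import Bounds, ObjectiveFn, RunHistory, evaluate_objective

LEVY_BETA = 1.5


@dataclass
class DFOConfig:
    n: int = 30
    iterations: int = 500
    seed: int = 0
    w_start: float = 0.9
    w_end: float = 0.4
    max_step_fraction: float = 0.1
    enemy_formula: str = "as_printed"  # or "outward"
    pollination: bool = False
    pollination_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise InputError("iterations must be >= 1")
        if self.n < 2:
            raise InputError("swarm size must be >= 2")
        if self.enemy_formula not in ("as_printed", "outward"):
            raise InputError("enemy_formula must be 'as_printed' or 'outward'")


@dataclass
class DragonflySwarm:
    positions: np.ndarray  # (n, d)
    steps: np.ndarray  # (n, d)
    food: np.ndarray  # (d,) best-so-far position
    enemy: np.ndarray  # (d,) worst position of the current iteration
    coefficients: tuple[float, float, float, float, float, float]  # s,a,c,f,e,w
    neighborhood_radius: float
    iteration: int = 0
    enemy_formula: str = "as_printed"

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def neighbors(self, i: int) -> np.ndarray:
        """Indices within neighborhood_radius (Euclidean), excluding i."""
        dist = np.linalg.norm(self.positions - self.positions[i], axis=1)
        idx = np.flatnonzero(dist <= self.neighborhood_radius)
        return idx[idx != i]


def idfo_initialize(n: int, bounds: Bounds, seed: int) -> DragonflySwarm:
    """Uniform per-dimension random initialization with zero steps."""
    if n < 2:
        raise InputError("swarm size must be >= 2")
    rng = np.random.default_rng(seed)
    positions = bounds.uniform(n, rng)
    d = bounds.dim
    return DragonflySwarm(
        positions=positions,
        steps=np.zeros((n, d)),
        food=positions[0].copy(),
        enemy=positions[0].copy(),
        coefficients=(0.0, 0.0, 0.0, 0.0, 0.0, 0.9),
        neighborhood_radius=float(np.max(bounds.range) / 4.0),
    )


def dfo_behaviors(
    swarm: DragonflySwarm, i: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The five behavior vectors (S, A, C, F, E) for individual i.

    With no neighbors S = A = C = 0; food/enemy terms are always defined.
    """
    x = swarm.positions[i]
    nbr = swarm.neighbors(i)
    d = swarm.dim
    if nbr.size == 0:
        S = A = C = np.zeros(d)
    else:
        S = -np.sum(x - swarm.positions[nbr], axis=0)
        A = swarm.steps[nbr].mean(axis=0)
        C = swarm.positions[nbr].mean(axis=0) - x
    F = swarm.food - x
    if swarm.enemy_formula == "as_printed":
        E = swarm.enemy + x
    else:
        E = swarm.enemy - x
    return S, A, C, F, E


def _levy(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Mantegna's heavy-tailed Levy step, beta = 1.5."""
    from scipy.special import gamma  # local import keeps numpy-only paths light

    beta = LEVY_BETA
    sigma = (
        gamma(1 + beta) * np.sin(np.pi * beta / 2)
        / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.normal(0, sigma, dim)
    v = rng.normal(0, 1, dim)
    return 0.01 * u / np.abs(v) ** (1 / beta)


def dfo_step(
    swarm: DragonflySwarm,
    bounds: Bounds,
    rng: np.random.Generator,
    max_step_fraction: float = 0.1,
) -> DragonflySwarm:
    """One synchronous position update of the whole swarm.

    Individuals with neighbors follow the five-behavior step rule with
    the step clipped elementwise to ``max_step_fraction`` of the box
    range; isolated individuals take a Levy flight around their current
    position with their step reset to zero.  All positions are clamped
    to the bounds afterwards.
    """
    s, a, c, f, e, w = swarm.coefficients
    max_step = max_step_fraction * bounds.range
    new_pos = swarm.positions.copy()
    new_steps = swarm.steps.copy()
    for i in range(swarm.n):
        nbr = swarm.neighbors(i)
        if nbr.size == 0:
            new_pos[i] = swarm.positions[i] + _levy(swarm.dim, rng) * swarm.positions[i]
            new_steps[i] = 0.0
            continue
        S, A, C, F, E = dfo_behaviors(swarm, i)
        step = s * S + a * A + c * C + f * F + e * E + w * swarm.steps[i]
        step = np.clip(step, -max_step, max_step)
        new_steps[i] = step
        new_pos[i] = swarm.positions[i] + step
    return DragonflySwarm(
        positions=bounds.clamp(new_pos),
        steps=new_steps,
        food=swarm.food.copy(),
        enemy=swarm.enemy.copy(),
        coefficients=swarm.coefficients,
        neighborhood_radius=swarm.neighborhood_radius,
        iteration=swarm.iteration + 1,
        enemy_formula=swarm.enemy_formula,
    )


def _schedule(t: int, T: int, cfg: DFOConfig, rng: np.random.Generator):
    """Per-iteration coefficients and neighborhood radius."""
    w = cfg.w_start - t * (cfg.w_start - cfg.w_end) / T
    r_t = max(0.0, 0.1 - t * 0.1 / (T / 2.0))
    s = 2.0 * rng.random() * r_t
    a = 2.0 * rng.random() * r_t
    c = 2.0 * rng.random() * r_t
    f = 2.0 * rng.random()
    e = r_t
    return (s, a, c, f, e, w)


def idfo_run(objective: ObjectiveFn, bounds: Bounds, config: DFOConfig | None = None) -> RunHistory:
    """Run the improved dragonfly optimizer; returns the best-so-far trace.

    Food tracks the best position seen so far; the enemy is the worst
    individual of the current iteration.
    """
    cfg = config or DFOConfig()
    rng = np.random.default_rng(cfg.seed)
    swarm = idfo_initialize(cfg.n, bounds, seed=int(rng.integers(2**31)))
    swarm.enemy_formula = cfg.enemy_formula
    history = RunHistory(seed=cfg.seed)
    T = cfg.iterations

    fitness = np.array([evaluate_objective(objective, x) for x in swarm.positions])
    history.evaluations += swarm.n
    best_i, worst_i = int(np.argmin(fitness)), int(np.argmax(fitness))
    swarm.food = swarm.positions[best_i].copy()
    food_fitness = float(fitness[best_i])
    swarm.enemy = swarm.positions[worst_i].copy()
    history.record(food_fitness, swarm.food)

    radius0 = np.max(bounds.range) / 4.0
    for t in range(1, T):
        swarm.coefficients = _schedule(t, T, cfg, rng)
        swarm.neighborhood_radius = float(radius0 + 2.0 * np.max(bounds.range) * t / T)
        swarm = dfo_step(swarm, bounds, rng, cfg.max_step_fraction)
        if cfg.pollination:
            # optional flower-pollination-style global move toward the food
            for i in range(swarm.n):
                if rng.random() < cfg.pollination_prob:
                    swarm.positions[i] += _levy(swarm.dim, rng) * (swarm.food - swarm.positions[i])
            swarm.positions = bounds.clamp(swarm.positions)
        fitness = np.array([evaluate_objective(objective, x) for x in swarm.positions])
        history.evaluations += swarm.n
        best_i, worst_i = int(np.argmin(fitness)), int(np.argmax(fitness))
        if fitness[best_i] < food_fitness:
            food_fitness = float(fitness[best_i])
            swarm.food = swarm.positions[best_i].copy()
        swarm.enemy = swarm.positions[worst_i].copy()
        history.record(food_fitness, swarm.food)
    return history
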