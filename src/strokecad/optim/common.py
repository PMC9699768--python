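"""Shared contracts for the continuous optimizers: box bounds, objective
wrapping, and the per-run history record."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..errors import InputError, RunError


@dataclass(frozen=True)
class Bounds:
    """Elementwise box constraints var_min < var_max."""

    var_min: np.ndarray
    var_max: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.var_min, dtype=float))
        hi = np.atleast_1d(np.asarray(self.var_max, dtype=float))
        if lo.shape != hi.shape:
            raise InputError("var_min and var_max must have equal shape")
        if not np.all(lo < hi):
            raise InputError("degenerate bounds: require var_min < var_max elementwise")
        object.__setattr__(self, "var_min", lo)
        object.__setattr__(self, "var_max", hi)

    @classmethod
    def cube(cls, lo: float, hi: float, dim: int) -> "Bounds":
        return cls(np.full(dim, float(lo)), np.full(dim, float(hi)))

    @property
    def dim(self) -> int:
        return self.var_min.size

    @property
    def range(self) -> np.ndarray:
        return self.var_max - self.var_min

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.var_min, self.var_max)

    def uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """x = var_min + (var_max - var_min) * U(0,1), independently per
        dimension — the uniform random initialization both optimizers use."""
        return self.var_min + self.range * rng.random((n, self.dim))


ObjectiveFn = Callable[[np.ndarray], float]


def evaluate_objective(objective: ObjectiveFn, x: np.ndarray) -> float:
    """Evaluate with the finite-value contract enforced."""
    value = float(objective(np.asarray(x, dtype=float)))
    if not np.isfinite(value):
        raise RunError(f"objective returned non-finite value {value} at x={np.asarray(x)}")
    return value


@dataclass
class RunHistory:
    """Best-so-far trace of one optimizer run.

    ``best_fitness_per_iteration`` records the running minimum, so it is
    non-increasing by construction (elitism).
    """

    best_fitness_per_iteration: list[float] = field(default_factory=list)
    best_position: np.ndarray | None = None
    evaluations: int = 0
    seed: int = 0

    @property
    def best_fitness(self) -> float:
        return self.best_fitness_per_iteration[-1]

    def record(self, fitness: float, position: np.ndarray) -> None:
        if not self.best_fitness_per_iteration or fitness < self.best_fitness:
            self.best_position = np.array(position, copy=True)
            self.best_fitness_per_iteration.append(float(fitness))
        else:
            self.best_fitness_per_iteration.append(self.best_fitness)

    def to_dict(self) -> dict:
        return {
            "best_fitness_per_iteration": [float(v) for v in self.best_fitness_per_iteration],
            "best_position": [float(v) for v in np.asarray(self.best_position)],
            "best_fitness": float(self.best_fitness),
            "evaluations": int(self.evaluations),
            "seed": int(self.seed),
        }


def sphere(x: np.ndarray) -> float:
    """Separable quadratic benchmark f(x) = sum(x^2); optimum 0 at origin."""
    return float(np.sum(np.square(x)))
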