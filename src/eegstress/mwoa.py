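"""Whale optimization algorithm (WOA) and its modified variant (MWOA).

WOA is a population metaheuristic mimicking humpback bubble-net
hunting. Each whale at iteration t either

* encircles the best-known position X*:  D = |C X* - X|, X' = X* - A D,
* spirals toward it:                     X' = |X* - X| e^{b l} cos(2 pi l) + X*,
* or explores toward a random whale:     D = |C Xr - X|, X' = Xr - A D,

with A = 2 a r1 - a, C = 2 r2, a decaying linearly 2 -> 0, and the
spiral/encircle switch decided by a fair coin p per whale per update.
Encircling exploits when |A| < 1 and exploration takes over when
|A| >= 1.

In the modified variant the uniform coefficients r1, r2 are replaced by
constants derived from the extreme fitness values of a preceding MBPSO
feature-selection run:

    r1 = (f_max + f_min) / 2,    r2 = (f_max - f_min) / 2.

Since fitnesses are held-out accuracies in [0, 1], both constants stay
in [0, 1]; A still shrinks through the a-schedule, so the algorithm
keeps its exploration-to-exploitation transition, but its coefficient
noise is pinned by how spread out the selection landscape was.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class SearchSpace:
    """A box in R^d."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D with equal shape")
        if not np.all(self.lower < self.upper):
            raise ValueError("need lower < upper elementwise")

    @property
    def dimension(self) -> int:
        return self.lower.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dimension))


@dataclass(frozen=True)
class WOAConfig:
    n_whales: int = 20
    n_iterations: int = 100
    b: float = 1.0  # spiral tightness
    mode: str = "woa"  # "woa" or "mwoa"
    fitness_bounds: tuple[float, float] | None = None  # (f_max, f_min), mwoa only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_whales < 1:
            raise ValueError("need at least 1 whale")
        if self.n_iterations < 1:
            raise ValueError("need at least 1 iteration")
        if self.mode not in ("woa", "mwoa"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "mwoa" and self.fitness_bounds is None:
            raise ValueError("mode='mwoa' requires fitness_bounds=(f_max, f_min)")


def coefficient_vectors(a: float, r1: float, r2: float) -> tuple[float, float]:
    """A = 2 a r1 - a and C = 2 r2."""
    return 2.0 * a * r1 - a, 2.0 * r2


def mwoa_random_pair(f_max: float, f_min: float) -> tuple[float, float]:
    """Fixed coefficient pair from selection-fitness extremes:
    r1 = (f_max + f_min)/2, r2 = (f_max - f_min)/2."""
    if f_min > f_max:
        raise ValueError(f"f_min={f_min} exceeds f_max={f_max}")
    return (f_max + f_min) / 2.0, (f_max - f_min) / 2.0


def encircle_update(X: np.ndarray, X_star: np.ndarray, A: float, C: float) -> np.ndarray:
    """Shrinking-encircling move toward the best position."""
    D = np.abs(C * X_star - X)
    return X_star - A * D


def spiral_update(X: np.ndarray, X_star: np.ndarray, b: float, l: float) -> np.ndarray:
    """Logarithmic-spiral move around the best position, l in [-1, 1]."""
    D = np.abs(X_star - X)
    return D * np.exp(b * l) * np.cos(2.0 * np.pi * l) + X_star


def exploration_update(X: np.ndarray, X_rand: np.ndarray, A: float, C: float) -> np.ndarray:
    """Exploration move toward a randomly chosen reference whale."""
    D = np.abs(C * X_rand - X)
    return X_rand - A * D


def run_optimizer(
    fitness_fn: Callable[[np.ndarray], float],
    space: SearchSpace,
    cfg: WOAConfig = WOAConfig(),
) -> tuple[np.ndarray, float, list[float]]:
    """Maximize ``fitness_fn`` over the box; returns (best_x, best_f, history).

    Deterministic given ``cfg.seed``. Positions are clamped to the box
    after every move. ``history`` holds the best fitness after the
    initial sampling and after each iteration (non-decreasing).
    """
    rng = np.random.default_rng(cfg.seed)

    def evaluate(x: np.ndarray) -> float:
        f = float(fitness_fn(x))
        if not np.isfinite(f):
            raise ValueError(f"fitness_fn returned non-finite value at {x.tolist()}")
        return f

    positions = space.sample(rng, cfg.n_whales)
    fitnesses = np.array([evaluate(x) for x in positions])
    best_i = int(np.argmax(fitnesses))
    best_x = positions[best_i].copy()
    best_f = float(fitnesses[best_i])
    history = [best_f]

    fixed_pair = None
    if cfg.mode == "mwoa":
        f_max, f_min = cfg.fitness_bounds
        fixed_pair = mwoa_random_pair(f_max, f_min)

    for t in range(cfg.n_iterations):
        a = 2.0 * (1.0 - t / cfg.n_iterations)
        for i in range(cfg.n_whales):
            p = rng.uniform()
            if p >= 0.5:
                l = rng.uniform(-1.0, 1.0)
                new = spiral_update(positions[i], best_x, cfg.b, l)
            else:
                if fixed_pair is not None:
                    r1, r2 = fixed_pair
                else:
                    r1, r2 = rng.uniform(), rng.uniform()
                A, C = coefficient_vectors(a, r1, r2)
                if abs(A) < 1.0:
                    new = encircle_update(positions[i], best_x, A, C)
                else:
                    j = int(rng.integers(cfg.n_whales))
                    new = exploration_update(positions[i], positions[j], A, C)
            positions[i] = space.clamp(new)
            fitnesses[i] = evaluate(positions[i])
            if fitnesses[i] > best_f:
                best_f = float(fitnesses[i])
                best_x = positions[i].copy()
        history.append(best_f)

    return best_x, best_f, history
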