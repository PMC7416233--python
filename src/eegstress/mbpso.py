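"""Modified binary particle swarm optimization (MBPSO) feature selection.

Each particle carries a binary position (a feature mask) and a real
velocity. Velocities follow the classical PSO update

    v_new = w v_old + c1 r1 (pbest - x) + c2 r2 (gbest - x)

with per-dimension uniform r1, r2, and are clamped to +-v_max. Binary
positions are resampled through the sigmoid transfer S(v) = 1/(1+e^-v):
bit d is set iff S(v_d) exceeds a fresh uniform draw. A wrapper fitness
(held-out classifier accuracy) scores each mask; personal and global
bests are tracked over the run, together with the extreme fitness
values f_max / f_min that the modified whale optimizer consumes as its
fixed coefficient pair.

A plain-PSO ablation variant (``transfer="round"``) keeps a continuous
position in [0, 1] and thresholds it at 0.5 instead of sampling
through the sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm settings. c1 = c2 = 2 is the classical social/cognitive
    weighting; inertia decays linearly 0.9 -> 0.4 over the run."""

    n_particles: int = 20
    n_iterations: int = 100
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 6.0
    target_cardinality: int | None = 10
    transfer: str = "sigmoid"  # "sigmoid" (MBPSO) or "round" (plain-PSO ablation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.n_iterations < 1:
            raise ValueError("need at least 1 iteration")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be non-negative")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.transfer not in ("sigmoid", "round"):
            raise ValueError(f"unknown transfer {self.transfer!r}")


@dataclass
class BinaryParticle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``fitness_max`` / ``fitness_min`` are the extremes over every mask
    evaluated during the run; they parameterize the modified whale
    optimizer downstream.
    """

    mask: np.ndarray
    gbest_fitness: float
    fitness_max: float
    fitness_min: float
    history: list[float] = field(default_factory=list)

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def selected_names(self, names) -> list[str]:
        return [names[i] for i in self.selected_indices]


def transfer_sigmoid(v):
    """Velocity -> selection probability, S(v) = 1/(1+e^-v)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def update_velocity(
    particle: BinaryParticle,
    gbest: np.ndarray,
    cfg: SwarmConfig,
    rng: np.random.Generator,
    w: float | None = None,
) -> np.ndarray:
    """One PSO velocity update, clamped to +-v_max."""
    x = particle.position.astype(float)
    if gbest.shape != x.shape:
        raise ValueError(f"dimension mismatch: gbest {gbest.shape} vs position {x.shape}")
    if w is None:
        w = cfg.w_start
    r1 = rng.uniform(size=x.shape)
    r2 = rng.uniform(size=x.shape)
    v = (
        w * particle.velocity
        + cfg.c1 * r1 * (particle.pbest_position - x)
        + cfg.c2 * r2 * (gbest - x)
    )
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(particle: BinaryParticle, rng: np.random.Generator) -> np.ndarray:
    """Sample a new binary position through the sigmoid transfer."""
    u = rng.uniform(size=particle.velocity.shape)
    return (transfer_sigmoid(particle.velocity) > u).astype(np.int8)


def _repair_empty(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # an empty mask cannot be scored by a wrapper classifier; flip one bit
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = 1
    return mask


def _inertia(cfg: SwarmConfig, t: int) -> float:
    if cfg.n_iterations == 1:
        return cfg.w_start
    return cfg.w_start + (cfg.w_end - cfg.w_start) * t / (cfg.n_iterations - 1)


def run_mbpso(
    fitness_fn: Callable[[np.ndarray], float],
    n_dims: int,
    cfg: SwarmConfig = SwarmConfig(),
) -> SelectionResult:
    """Run the swarm over {0,1}^n_dims, maximizing ``fitness_fn(mask)``.

    Deterministic given ``cfg.seed``. If ``cfg.target_cardinality`` is
    set, the returned mask is repaired to exactly that many features by
    keeping the dimensions most frequently selected across the final
    swarm (ties broken toward the lower index); ``gbest_fitness`` still
    refers to the unconstrained best mask found.
    """
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    rng = np.random.default_rng(cfg.seed)

    def evaluate(mask: np.ndarray) -> float:
        f = float(fitness_fn(mask))
        if not np.isfinite(f):
            raise ValueError(f"fitness_fn returned non-finite value for mask {mask.tolist()}")
        return f

    particles: list[BinaryParticle] = []
    f_max = -np.inf
    f_min = np.inf
    gbest = None
    gbest_fit = -np.inf
    for _ in range(cfg.n_particles):
        pos = _repair_empty((rng.uniform(size=n_dims) < 0.5).astype(np.int8), rng)
        vel = rng.uniform(-1.0, 1.0, size=n_dims)
        fit = evaluate(pos)
        f_max = max(f_max, fit)
        f_min = min(f_min, fit)
        particles.append(BinaryParticle(pos, vel, pos.copy(), fit))
        if fit > gbest_fit:
            gbest_fit, gbest = fit, pos.copy()

    history = [gbest_fit]
    cont = None
    if cfg.transfer == "round":
        cont = np.vstack([p.position.astype(float) for p in particles])

    for t in range(cfg.n_iterations):
        w = _inertia(cfg, t)
        for i, p in enumerate(particles):
            p.velocity = update_velocity(p, gbest, cfg, rng, w=w)
            if cfg.transfer == "sigmoid":
                p.position = _repair_empty(update_position(p, rng), rng)
            else:
                cont[i] = np.clip(cont[i] + p.velocity, 0.0, 1.0)
                p.position = _repair_empty((cont[i] >= 0.5).astype(np.int8), rng)
            fit = evaluate(p.position)
            f_max = max(f_max, fit)
            f_min = min(f_min, fit)
            if fit > p.pbest_fitness:
                p.pbest_fitness = fit
                p.pbest_position = p.position.copy()
            if fit > gbest_fit:
                gbest_fit, gbest = fit, p.position.copy()
        history.append(gbest_fit)

    mask = gbest.copy()
    if cfg.target_cardinality is not None:
        k = min(cfg.target_cardinality, n_dims)
        freq = np.mean([p.position for p in particles], axis=0)
        order = np.lexsort((np.arange(n_dims), -freq))  # high freq first, low index on ties
        mask = np.zeros(n_dims, dtype=np.int8)
        mask[order[:k]] = 1

    return SelectionResult(
        mask=mask,
        gbest_fitness=gbest_fit,
        fitness_max=f_max,
        fitness_min=f_min,
        history=history,
    )
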