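"""Binary PSO: transfer function, updates, and optimum recovery."""

import itertools

import numpy as np
import pytest

from eegstress.mbpso import (
    BinaryParticle,
    SwarmConfig,
    run_mbpso,
    transfer_sigmoid,
    update_position,
    update_velocity,
)


class _FixedRng:
    """Stub RNG returning a constant for uniform draws."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.full(size, self.value) if size is not None else self.value


def _particle(position, velocity, pbest):
    return BinaryParticle(
        position=np.array(position, dtype=np.int8),
        velocity=np.array(velocity, dtype=float),
        pbest_position=np.array(pbest, dtype=np.int8),
        pbest_fitness=0.0,
    )


def test_velocity_update_degenerate_terms():
    p = _particle([1, 0, 1], [0.5, -0.5, 1.0], [1, 0, 1])
    g = np.array([1, 0, 1])
    cfg = SwarmConfig(c1=0.0, c2=0.0)
    v = update_velocity(p, g, cfg, np.random.default_rng(0), w=0.0)
    np.testing.assert_array_equal(v, np.zeros(3))
    # x == pbest == gbest: difference terms vanish for any r
    v2 = update_velocity(p, g, SwarmConfig(), np.random.default_rng(0), w=1.0)
    np.testing.assert_allclose(v2, p.velocity)


def test_velocity_update_direct_substitution():
    # v = 1*0 + 2*0.5*(pbest-x) + 2*0.5*(gbest-x) with pbest-x=1, gbest-x=2 -> 3
    p = _particle([0, 0], [0.0, 0.0], [1, 1])
    g = np.array([2, 2])  # difference of 2 per dimension
    v = update_velocity(p, g, SwarmConfig(v_max=10.0), _FixedRng(0.5), w=1.0)
    np.testing.assert_allclose(v, [3.0, 3.0])


def test_velocity_clamped_to_vmax():
    p = _particle([0, 0], [0.0, 0.0], [1, 1])
    g = np.array([5, 5])
    v = update_velocity(p, g, SwarmConfig(v_max=2.0), _FixedRng(1.0), w=1.0)
    assert np.all(np.abs(v) <= 2.0)


def test_velocity_dimension_mismatch():
    p = _particle([0, 0], [0.0, 0.0], [1, 1])
    with pytest.raises(ValueError):
        update_velocity(p, np.array([1, 1, 1]), SwarmConfig(), np.random.default_rng(0))


def test_transfer_sigmoid_values():
    assert transfer_sigmoid(0.0) == 0.5
    assert transfer_sigmoid(20.0) > 0.999999
    v = np.random.default_rng(3).normal(size=50)
    np.testing.assert_allclose(transfer_sigmoid(-v), 1.0 - transfer_sigmoid(v), atol=1e-12)


def test_position_update_saturation_and_balance():
    rng = np.random.default_rng(0)
    p = _particle([0] * 8, [20.0] * 8, [0] * 8)
    assert update_position(p, rng).tolist() == [1] * 8
    p.velocity = np.full(8, -20.0)
    assert update_position(p, rng).tolist() == [0] * 8
    # zero velocity: each bit is a fair coin
    p.velocity = np.zeros(8)
    draws = np.array([update_position(p, rng) for _ in range(10000)])
    freq = draws.mean(axis=0)
    assert np.all((freq > 0.48) & (freq < 0.52))


def test_constant_fitness_landscape():
    result = run_mbpso(
        lambda m: 0.7,
        n_dims=6,
        cfg=SwarmConfig(n_particles=4, n_iterations=5, target_cardinality=None, seed=1),
    )
    assert result.gbest_fitness == 0.7
    assert result.fitness_max == 0.7
    assert result.fitness_min == 0.7


def test_bitmatch_landscape_recovery():
    """D=4 bit-match: exhaustive enumeration confirms the unique optimum,
    and the swarm finds it in at least 18 of 20 seeds."""
    target = np.array([1, 0, 1, 0], dtype=np.int8)

    def fitness(mask):
        return float(np.mean(mask == target))

    # exhaustive oracle over all 16 masks: the target is the unique argmax
    best = max(
        (np.array(bits, dtype=np.int8) for bits in itertools.product([0, 1], repeat=4)),
        key=fitness,
    )
    scores = sorted(
        fitness(np.array(b, dtype=np.int8)) for b in itertools.product([0, 1], repeat=4)
    )
    assert fitness(best) == 1.0 and scores[-2] < 1.0

    hits = 0
    for seed in range(20):
        res = run_mbpso(
            fitness,
            n_dims=4,
            cfg=SwarmConfig(n_particles=10, n_iterations=50, target_cardinality=None, seed=seed),
        )
        hits += int(np.array_equal(res.mask, target))
    assert hits >= 18


def test_history_monotone_and_bounds():
    rng_fit = np.random.default_rng(7)
    values = {}

    def fitness(mask):
        key = tuple(mask.tolist())
        if key not in values:
            values[key] = float(rng_fit.uniform())
        return values[key]

    res = run_mbpso(fitness, n_dims=8, cfg=SwarmConfig(n_particles=6, n_iterations=20, seed=3))
    hist = np.array(res.history)
    assert np.all(np.diff(hist) >= 0)
    assert res.fitness_min <= hist.min() and hist.max() <= res.fitness_max
    assert int(res.mask.sum()) == 8  # default target cardinality 10 capped at n_dims


def test_target_cardinality_repair():
    res = run_mbpso(
        lambda m: float(np.sum(m)) / m.size,
        n_dims=12,
        cfg=SwarmConfig(n_particles=8, n_iterations=10, target_cardinality=5, seed=0),
    )
    assert int(res.mask.sum()) == 5


def test_same_seed_bit_identical():
    def fitness(mask):
        return float(np.sum(mask * np.arange(1, 7)) / 21.0)

    cfg = SwarmConfig(n_particles=5, n_iterations=15, seed=11)
    a = run_mbpso(fitness, 6, cfg)
    b = run_mbpso(fitness, 6, cfg)
    np.testing.assert_array_equal(a.mask, b.mask)
    assert a.history == b.history
    assert (a.fitness_max, a.fitness_min) == (b.fitness_max, b.fitness_min)


def test_non_finite_fitness_rejected():
    with pytest.raises(ValueError, match="non-finite"):
        run_mbpso(lambda m: float("nan"), 4, SwarmConfig(n_particles=2, n_iterations=1, seed=0))


def test_plain_pso_variant_runs_and_recovers_easy_optimum():
    target = np.array([1, 1, 0, 0], dtype=np.int8)

    def fitness(mask):
        return float(np.mean(mask == target))

    hits = 0
    for seed in range(10):
        res = run_mbpso(
            fitness,
            4,
            SwarmConfig(
                n_particles=10, n_iterations=50, target_cardinality=None,
                transfer="round", seed=seed,
            ),
        )
        hits += int(np.array_equal(res.mask, target))
    assert hits >= 6
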