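"""Kernel encoding, wrapper fitness, whale-tuned SVM, stress levels."""

import numpy as np
import pytest

from eegstress.classify import (
    DEFAULT_KERNEL_SPACE,
    KernelSpec,
    SplitSpec,
    STRESS_LEVELS,
    assign_stress_levels,
    encode_position_to_kernel,
    fitness_accuracy,
    optimize_and_train,
    predict_stress,
    train_test_indices,
)
from eegstress.mwoa import WOAConfig
from eegstress.synth import generate_labeled_dataset


def xor_dataset(n_per_quadrant=30, seed=0):
    """Four Gaussian clusters at (+-1, +-1); label = sign of x1*x2.

    Symmetric under x -> -x, so only the RBF kernel (of the four, with
    coef0=0) can separate it."""
    rng = np.random.default_rng(seed)
    centers = [(1, 1), (-1, -1), (1, -1), (-1, 1)]
    X, y = [], []
    for cx, cy in centers:
        pts = rng.normal([cx, cy], 0.25, size=(n_per_quadrant, 2))
        X.append(pts)
        y.extend([int(cx * cy > 0)] * n_per_quadrant)
    return np.vstack(X), np.array(y)


def test_kernel_spec_validation():
    with pytest.raises(ValueError):
        KernelSpec(kernel="quartic", C=1.0, gamma=0.1)
    with pytest.raises(ValueError):
        KernelSpec(kernel="rbf", C=-1.0, gamma=0.1)


def test_encode_position_decoding_rule():
    spec = encode_position_to_kernel(np.array([2.7, 0.0, -1.0]))
    assert spec == KernelSpec(kernel="rbf", C=1.0, gamma=0.1)
    spec = encode_position_to_kernel(np.array([0.0, 3.0, 1.0]))
    assert spec.kernel == "linear" and spec.C == 1000.0 and spec.gamma == 10.0
    assert encode_position_to_kernel(np.array([3.999, 0.0, 0.0])).kernel == "sigmoid"
    # out-of-box input is clamped, never an error
    assert encode_position_to_kernel(np.array([4.2, 5.0, -9.0])).kernel == "sigmoid"
    assert encode_position_to_kernel(np.array([-1.0, 0.0, 0.0])).kernel == "linear"


def test_split_is_seeded_and_sized():
    y = np.tile([0, 1], 25)
    subjects = np.repeat(["a", "b"], 25)
    split = SplitSpec(train_files_per_subject=18, test_files_per_subject=7, seed=5)
    tr, te = train_test_indices(y, split, subjects)
    assert len(tr) == 36 and len(te) == 14
    assert set(tr).isdisjoint(te)
    tr2, te2 = train_test_indices(y, split, subjects)
    np.testing.assert_array_equal(tr, tr2)
    np.testing.assert_array_equal(te, te2)
    with pytest.raises(ValueError, match="has 25 files"):
        train_test_indices(y, SplitSpec(train_files_per_subject=20, test_files_per_subject=7), subjects)


def test_fitness_is_one_on_separable_data():
    X, y, _ = generate_labeled_dataset(50, 4, [0, 1], effect_size=6.0, seed=2)
    spec = KernelSpec(kernel="linear", C=1.0, gamma=0.1)
    fit = fitness_accuracy(X, y, np.array([1, 1, 0, 0]), spec, SplitSpec(seed=3))
    assert fit == 1.0


def test_fitness_near_chance_on_uninformative_features():
    X, y, _ = generate_labeled_dataset(1800, 2, [], effect_size=0.0, seed=4)
    spec = KernelSpec(kernel="linear", C=1.0, gamma=0.1)
    fit = fitness_accuracy(X, y, np.array([1, 1]), spec, SplitSpec(seed=5))
    assert 0.44 <= fit <= 0.56


def test_fitness_rejects_empty_mask_and_requires_two_classes():
    X, y, _ = generate_labeled_dataset(20, 3, [0], effect_size=1.0, seed=6)
    spec = KernelSpec(kernel="linear", C=1.0, gamma=0.1)
    with pytest.raises(ValueError, match="no features"):
        fitness_accuracy(X, y, np.zeros(3), spec, SplitSpec(seed=0))
    with pytest.raises(ValueError, match="single-class"):
        fitness_accuracy(X, np.zeros_like(y), np.array([1, 0, 0]), spec, SplitSpec(seed=0))


def test_optimizer_selects_rbf_on_xor():
    """Exhaustive kernel-grid oracle shows RBF strictly dominates on the
    XOR layout; the whale-driven search should agree in >= 16/20 seeds."""
    X, y = xor_dataset(seed=1)
    mask = np.array([1, 1])
    split = SplitSpec(seed=7)

    # oracle: best accuracy per kernel over a log grid of C and gamma
    grid = {}
    for kernel in ("linear", "poly", "rbf", "sigmoid"):
        best = 0.0
        for logc in (-2, 0, 2):
            for logg in (-2, -1, 0):
                spec = KernelSpec(kernel=kernel, C=10.0**logc, gamma=10.0**logg)
                best = max(best, fitness_accuracy(X, y, mask, spec, split))
        grid[kernel] = best
    assert grid["rbf"] == 1.0
    assert all(grid[k] < grid["rbf"] for k in ("linear", "poly", "sigmoid"))

    hits = 0
    for seed in range(20):
        cfg = WOAConfig(n_whales=12, n_iterations=15, seed=seed)
        _, spec, fit = optimize_and_train(X, y, mask, cfg, split)
        hits += int(spec.kernel == "rbf")
    assert hits >= 16


def test_optimized_fitness_beats_fixed_baseline():
    X, y, _ = generate_labeled_dataset(40, 6, [0, 3], effect_size=1.5, seed=8)
    mask = np.ones(6)
    split = SplitSpec(seed=9)
    baseline = fitness_accuracy(X, y, mask, KernelSpec("linear", 1.0, 0.1), split)
    cfg = WOAConfig(n_whales=10, n_iterations=15, mode="mwoa", fitness_bounds=(0.9, 0.6), seed=10)
    _, _, best = optimize_and_train(X, y, mask, cfg, split)
    assert best >= baseline


def test_predict_stress_contract():
    X, y, _ = generate_labeled_dataset(30, 3, [0], effect_size=5.0, seed=11)
    spec = KernelSpec(kernel="linear", C=1.0, gamma=0.1)
    model = spec.build()
    model.fit(X, y)
    pred = predict_stress(model, X)
    assert set(pred) <= set(y)
    assert predict_stress(model, np.empty((0, 3))).size == 0
    # a separable model reproduces its training labels
    assert np.mean(pred == y) == 1.0


def test_stress_levels_quartile_binning():
    scores = np.arange(1, 13, dtype=float)
    levels = assign_stress_levels(scores)
    assert levels == (
        ["no stress"] * 3 + ["low"] * 3 + ["medium"] * 3 + ["high"] * 3
    )
    assert set(assign_stress_levels(np.zeros(5))) == {"no stress"}
    rng = np.random.default_rng(12)
    random_levels = assign_stress_levels(rng.normal(size=40))
    assert set(random_levels) <= set(STRESS_LEVELS)


def test_stress_levels_monotone_in_score(rng):
    scores = rng.normal(size=25)
    levels = assign_stress_levels(scores)
    rank = {lev: i for i, lev in enumerate(STRESS_LEVELS)}
    order = np.argsort(scores)
    ranks = [rank[levels[i]] for i in order]
    assert all(a <= b for a, b in zip(ranks, ranks[1:]))
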