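"""SVM stress classifier with whale-optimized kernel selection.

The SVM itself is scikit-learn's ``SVC`` behind a thin contract
(train / predict / decision score); the bespoke parts are

* the encoding that maps a continuous 3-vector searched by the whale
  optimizer onto a discrete kernel choice plus log-scaled C and gamma,
* the wrapper fitness, held-out accuracy (tp+tn)/(tp+tn+fp+fn) on a
  seeded per-subject file split (18 train / 7 test by default),
* the mapping of signed decision scores to four ordered stress levels
  (no / low / medium / high) by quartile thresholds.

Features are standardized inside the fitted pipeline (fit on the
training partition only) since SVM kernels are scale-sensitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from eegstress.mwoa import SearchSpace, WOAConfig, run_optimizer

KERNELS = ("linear", "poly", "rbf", "sigmoid")

#: Search box for kernel selection: [kernel index, log10 C, log10 gamma].
DEFAULT_KERNEL_SPACE = SearchSpace(lower=[0.0, -3.0, -4.0], upper=[4.0, 3.0, 1.0])

STRESS_LEVELS = ("no stress", "low", "medium", "high")


@dataclass(frozen=True)
class KernelSpec:
    """A fully specified SVM kernel configuration."""

    kernel: str
    C: float
    gamma: float
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.degree < 2:
            raise ValueError("degree must be >= 2")

    def build(self) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    SVC(
                        kernel=self.kernel,
                        C=self.C,
                        gamma=self.gamma,
                        degree=self.degree,
                        # wrapper search visits pathological (C, gamma)
                        # corners where libsvm converges extremely
                        # slowly on inseparable data; a deterministic
                        # iteration cap keeps every candidate cheap
                        max_iter=20_000,
                    ),
                ),
            ]
        )


@dataclass(frozen=True)
class SplitSpec:
    """Per-subject file-wise train/test split (18/7 by default)."""

    train_files_per_subject: int = 18
    test_files_per_subject: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_files_per_subject < 1 or self.test_files_per_subject < 1:
            raise ValueError("both partitions need at least one file")


def encode_position_to_kernel(x: np.ndarray, space: SearchSpace = DEFAULT_KERNEL_SPACE) -> KernelSpec:
    """Decode an optimizer position into a KernelSpec.

    x[0] in [0, 4) picks the kernel by its floor; x[1] and x[2] are
    log10 of C and gamma. Out-of-box coordinates are clamped.
    """
    x = space.clamp(np.asarray(x, dtype=float))
    k = min(int(np.floor(x[0])), len(KERNELS) - 1)
    return KernelSpec(kernel=KERNELS[k], C=float(10.0 ** x[1]), gamma=float(10.0 ** x[2]))


def train_test_indices(
    y: np.ndarray,
    split: SplitSpec,
    subjects: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded file-wise split, per subject when subject ids are given.

    Within each subject the files are shuffled and the first
    ``train_files_per_subject`` go to training, the next
    ``test_files_per_subject`` to testing. Without subject ids, a
    single stratified shuffle at the same train:test ratio is used.
    """
    rng = np.random.default_rng(split.seed)
    y = np.asarray(y)
    if subjects is not None:
        subjects = np.asarray(subjects)
        train_idx, test_idx = [], []
        for s in np.unique(subjects):
            idx = np.flatnonzero(subjects == s)
            need = split.train_files_per_subject + split.test_files_per_subject
            if idx.size < need:
                raise ValueError(
                    f"subject {s!r} has {idx.size} files; split needs {need}"
                )
            idx = rng.permutation(idx)
            train_idx.extend(idx[: split.train_files_per_subject])
            test_idx.extend(
                idx[split.train_files_per_subject : split.train_files_per_subject + split.test_files_per_subject]
            )
        return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))

    frac_test = split.test_files_per_subject / (
        split.train_files_per_subject + split.test_files_per_subject
    )
    # stratified: shuffle within each class, take the tail of each as test
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        n_test = max(1, int(round(frac_test * idx.size)))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def fitness_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    spec: KernelSpec,
    split: SplitSpec,
    subjects: np.ndarray | None = None,
) -> float:
    """Held-out accuracy of ``spec`` on the masked features.

    This is the objective both metaheuristics maximize. Deterministic
    given the split seed and spec.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mask = np.asarray(mask).astype(bool)
    if mask.size != X.shape[1]:
        raise ValueError(f"mask length {mask.size} != {X.shape[1]} features")
    if not mask.any():
        raise ValueError("mask selects no features")
    tr, te = train_test_indices(y, split, subjects)
    if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
        raise ValueError("single-class partition; re-split with a different seed")
    model = spec.build()
    model.fit(X[np.ix_(tr, np.flatnonzero(mask))], y[tr])
    pred = model.predict(X[np.ix_(te, np.flatnonzero(mask))])
    return float(np.mean(pred == y[te]))


def optimize_and_train(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    woa_cfg: WOAConfig,
    split: SplitSpec,
    subjects: np.ndarray | None = None,
    space: SearchSpace = DEFAULT_KERNEL_SPACE,
) -> tuple[Pipeline, KernelSpec, float]:
    """Search kernel space with the whale optimizer, then refit.

    Returns the model refitted on the full training partition with the
    best kernel found, the decoded KernelSpec, and its held-out
    fitness.
    """

    def objective(pos: np.ndarray) -> float:
        return fitness_accuracy(X, y, mask, encode_position_to_kernel(pos, space), split, subjects)

    best_x, best_f, _ = run_optimizer(objective, space, woa_cfg)
    spec = encode_position_to_kernel(best_x, space)
    tr, _ = train_test_indices(y, split, subjects)
    model = spec.build()
    sel = np.flatnonzero(np.asarray(mask).astype(bool))
    model.fit(np.asarray(X, dtype=float)[np.ix_(tr, sel)], np.asarray(y)[tr])
    return model, spec, best_f


def predict_stress(model: Pipeline, X_new: np.ndarray) -> np.ndarray:
    """Class label per row (empty input allowed)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[0] == 0:
        return np.array([])
    return model.predict(X_new)


def decision_scores(model: Pipeline, X_new: np.ndarray) -> np.ndarray:
    """Signed distance to the separating surface, one value per row."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[0] == 0:
        return np.array([])
    return model.decision_function(X_new)


def assign_stress_levels(scores: np.ndarray, n_levels: int = 4) -> list[str]:
    """Bin decision scores into ordered stress levels by quartiles.

    Thresholds are the 25/50/75 percentiles of the given score
    distribution; higher score never maps to a lower level. With fewer
    than 4 distinct scores the ties collapse into the lower bins (all
    equal scores -> everything "no stress").
    """
    if n_levels != len(STRESS_LEVELS):
        raise ValueError(f"only {len(STRESS_LEVELS)} levels supported")
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite score")
    qs = np.quantile(scores, [0.25, 0.5, 0.75])
    out = []
    for s in scores:
        level = int(np.sum(s > qs))
        out.append(STRESS_LEVELS[level])
    return out


def save_model_spec(path, spec: KernelSpec, mask: np.ndarray, seed: int) -> None:
    """Persist the chosen kernel + mask as JSON (the model refits from these)."""
    payload = {"spec": asdict(spec), "mask": np.asarray(mask).astype(int).tolist(), "seed": seed}
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def load_model_spec(path) -> tuple[KernelSpec, np.ndarray, int]:
    with open(path) as f:
        payload = json.load(f)
    return KernelSpec(**payload["spec"]), np.array(payload["mask"], dtype=np.int8), payload["seed"]
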