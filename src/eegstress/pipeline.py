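"""End-to-end pipeline: preprocess -> extract -> select -> train -> evaluate.

Every run writes its intermediate artifacts (cleaned recordings,
feature table, selection mask, model spec, metrics) plus a run log
holding the config snapshot and all derived seeds, so a run can be
replayed exactly or a single stage replayed in isolation.

One global seed drives everything. Per-stage seeds derive from it by a
fixed affine scheme (seed * 10007 + stage offset, mod 2^31), so two
ablation variants started from the same global seed see identical data
and identical splits — any metric difference is attributable to the
algorithm variant alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from eegstress.classify import (
    KernelSpec,
    SplitSpec,
    assign_stress_levels,
    decision_scores,
    fitness_accuracy,
    optimize_and_train,
    predict_stress,
    train_test_indices,
)
from eegstress.features import FEATURE_NAMES, feature_table, features_from_recording
from eegstress.mbpso import SwarmConfig, run_mbpso
from eegstress.metrics import MetricSet, compute_metrics, confusion_counts, metrics_table
from eegstress.mwoa import WOAConfig
from eegstress.nlms import NLMSConfig, remove_eye_blinks
from eegstress.signal_io import read_recording_csv, write_recording_csv
from eegstress.synth import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)

VARIANTS = ("mbpso+mwoa", "mbpso+woa", "pso+mwoa", "mbpso-only")

_STAGE_OFFSETS = {"synth": 1, "split": 2, "mbpso": 3, "mwoa": 4}

#: Fixed classifier used inside the selection wrapper fitness (kernel
#: search happens later, on the selected subset).
SELECTION_KERNEL = KernelSpec(kernel="linear", C=1.0, gamma=0.1)

#: Baseline kernel for the no-optimizer ablation.
BASELINE_KERNEL = KernelSpec(kernel="linear", C=1.0, gamma=0.1)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed (documented fixed offset scheme)."""
    return (global_seed * 10007 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    nlms: NLMSConfig = field(default_factory=NLMSConfig)
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    woa: WOAConfig = field(default_factory=WOAConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    synth: SynthConfig = field(default_factory=SynthConfig)
    variant: str = "mbpso+mwoa"
    reference_channels: tuple[str, ...] = ("Fp1", "Fp2")
    out_dir: str = "run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")


def _log_stage(name: str, t0: float, **info) -> None:
    logger.info("stage=%s duration=%.2fs %s", name, time.time() - t0, json.dumps(info, default=str))


def extract_feature_dataframe(records, cfg: PipelineConfig, out_dir: Path | None = None) -> pd.DataFrame:
    """Clean every recording and compute its per-file feature vector."""
    vectors = []
    for rec, label in records:
        t0 = time.time()
        cleaned = remove_eye_blinks(rec, cfg.nlms, list(cfg.reference_channels))
        if out_dir is not None:
            write_recording_csv(cleaned, out_dir / f"clean_{rec.file_id}.csv")
        fv = features_from_recording(cleaned)
        fv.label = label
        vectors.append(fv)
        _log_stage("preprocess+extract", t0, file_id=rec.file_id)
    return feature_table(vectors)


def run_pipeline(cfg: PipelineConfig, features: pd.DataFrame | None = None) -> dict:
    """Run the staged flow; returns a run report dict.

    If ``features`` is None, a synthetic dataset is generated from
    ``cfg.synth`` (with a seed derived from the global seed) and taken
    through preprocessing and feature extraction; otherwise the given
    feature table (24 canonical columns + subject_id/file_id/label) is
    used directly.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- data ---------------------------------------------------------
    if features is None:
        t0 = time.time()
        synth_cfg = dataclasses.replace(cfg.synth, seed=stage_seed(cfg.seed, "synth"))
        records = [(rec, label) for rec, label, _ in generate_dataset(synth_cfg)]
        _log_stage("simulate", t0, n_files=len(records))
        features = extract_feature_dataframe(records, cfg, out_dir=None)
    features = features.copy()
    features.to_csv(out / "features.csv", index=False)

    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = features["label"].to_numpy()
    subjects = features["subject_id"].to_numpy()
    split = dataclasses.replace(cfg.split, seed=stage_seed(cfg.seed, "split"))

    # --- feature selection -------------------------------------------
    t0 = time.time()
    transfer = "round" if cfg.variant == "pso+mwoa" else "sigmoid"
    swarm_cfg = dataclasses.replace(
        cfg.swarm, transfer=transfer, seed=stage_seed(cfg.seed, "mbpso")
    )

    def selection_fitness(mask: np.ndarray) -> float:
        return fitness_accuracy(X, y, mask, SELECTION_KERNEL, split, subjects=subjects)

    selection = run_mbpso(selection_fitness, X.shape[1], swarm_cfg)
    mask = selection.mask
    with open(out / "mask.json", "w") as f:
        json.dump(
            {
                "selected": selection.selected_names(list(FEATURE_NAMES)),
                "mask": mask.astype(int).tolist(),
                "gbest_fitness": selection.gbest_fitness,
                "f_max": selection.fitness_max,
                "f_min": selection.fitness_min,
            },
            f,
            indent=2,
        )
    _log_stage("select", t0, variant=transfer, gbest=selection.gbest_fitness)

    # --- kernel search + training ------------------------------------
    t0 = time.time()
    if cfg.variant == "mbpso-only":
        spec = BASELINE_KERNEL
        best_fitness = fitness_accuracy(X, y, mask, spec, split, subjects=subjects)
        model = spec.build()
        tr, _ = train_test_indices(y, split, subjects)
        model.fit(X[np.ix_(tr, np.flatnonzero(mask))], y[tr])
    else:
        mode = "woa" if cfg.variant == "mbpso+woa" else "mwoa"
        bounds = None if mode == "woa" else (selection.fitness_max, selection.fitness_min)
        woa_cfg = dataclasses.replace(
            cfg.woa, mode=mode, fitness_bounds=bounds, seed=stage_seed(cfg.seed, "mwoa")
        )
        model, spec, best_fitness = optimize_and_train(
            X, y, mask, woa_cfg, split, subjects=subjects
        )
    with open(out / "model.json", "w") as f:
        json.dump(
            {
                "kernel": spec.kernel,
                "C": spec.C,
                "gamma": spec.gamma,
                "degree": spec.degree,
                "mask": mask.astype(int).tolist(),
                "seed": cfg.seed,
                "fitness": best_fitness,
            },
            f,
            indent=2,
        )
    _log_stage("train", t0, kernel=spec.kernel, fitness=best_fitness)

    # --- evaluation ---------------------------------------------------
    t0 = time.time()
    tr, te = train_test_indices(y, split, subjects)
    sel = np.flatnonzero(mask)
    pred = predict_stress(model, X[np.ix_(te, sel)])
    scores = decision_scores(model, X[np.ix_(te, sel)])
    positive = sorted(np.unique(y))[-1]

    per_subject: dict[str, MetricSet] = {}
    for s in np.unique(subjects):
        in_s = subjects[te] == s
        counts = confusion_counts(y[te][in_s], pred[in_s], positive)
        per_subject[str(s)] = compute_metrics(counts)
    table = metrics_table(per_subject, method=cfg.variant)
    table.to_csv(out / "metrics.csv", index=False, float_format="%.6f")

    levels = assign_stress_levels(scores)
    pred_df = pd.DataFrame(
        {
            "file_id": features["file_id"].to_numpy()[te],
            "predicted": pred,
            "score": np.round(scores, 6),
            "stress_level": levels,
        }
    )
    pred_df.to_csv(out / "predictions.csv", index=False)
    _log_stage("evaluate", t0, n_test=len(te))

    report = {
        "variant": cfg.variant,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGE_OFFSETS},
        "selected_features": selection.selected_names(list(FEATURE_NAMES)),
        "f_max": selection.fitness_max,
        "f_min": selection.fitness_min,
        "kernel": {"kernel": spec.kernel, "C": spec.C, "gamma": spec.gamma, "degree": spec.degree},
        "fitness": best_fitness,
        "average_metrics": table[table["subject"] == "average"].iloc[0][
            ["accuracy", "sensitivity", "specificity", "f1"]
        ].to_dict(),
    }
    with open(out / "run_report.json", "w") as f:
        json.dump(report, f, indent=2)
    return report


def heuristic_stress_labels(records: list) -> list[int]:
    """Demo-only labeler for unlabeled real recordings.

    Labels a file "stressed" (1) if its mean frontal beta-band
    (13-30 Hz) power, after blink removal, exceeds the median across
    that subject's files; otherwise "calm" (0). This is a convenience
    heuristic for exercising the pipeline on recordings without ground
    truth — it is not part of the benchmarked method and carries no
    claim of physiological validity.
    """
    from scipy import signal as sp_signal

    from eegstress.features import BANDS

    powers, subjects = [], []
    for rec in records:
        cleaned = remove_eye_blinks(rec)
        frontal = [
            i
            for i, lab in enumerate(cleaned.channel_labels)
            if lab.startswith("F") and lab not in ("Fp1", "Fp2")
        ] or list(range(cleaned.n_channels))
        nyq = cleaned.rate / 2.0
        lo, hi = BANDS["beta"]
        sos = sp_signal.butter(4, [lo / nyq, min(hi, 0.99 * nyq) / nyq], btype="band", output="sos")
        beta = sp_signal.sosfiltfilt(sos, cleaned.data[frontal], axis=1)
        powers.append(float(np.mean(beta**2)))
        subjects.append(rec.subject_id)
    powers = np.asarray(powers)
    subjects = np.asarray(subjects)
    labels = np.zeros(len(records), dtype=int)
    for s in np.unique(subjects):
        in_s = subjects == s
        labels[in_s] = (powers[in_s] > np.median(powers[in_s])).astype(int)
    return labels.tolist()


def load_feature_csv(path) -> pd.DataFrame:
    """Read a feature table written by :func:`extract_feature_dataframe`."""
    df = pd.read_csv(path)
    missing = [c for c in list(FEATURE_NAMES) + ["subject_id", "file_id", "label"] if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns: {missing}")
    return df
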