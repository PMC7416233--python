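"""Synthetic multichannel EEG with known ground truth.

The generator emulates the kind of recording the pipeline targets:
32 channels in a 10-20 montage at 1000 Hz, with

* a 1/f ("pink") background per channel, scaled to a ~10 uV RMS,
* stereotyped eye blinks — 300 ms biphasic raised-cosine pulses placed
  at Poisson times, full amplitude on Fp1/Fp2 and decaying
  exponentially with scalp row distance from the frontal row — whose
  exact sample windows are returned as ground truth for artifact-
  removal scoring,
* a class-dependent band-power shift on posterior channels: "stressed"
  files gain beta-band (13-30 Hz) power, "calm" files gain alpha-band
  (8-13 Hz) power, which is what the occipital feature bank picks up.

It is not a physiological simulator: no ERPs, no behavioral structure,
no inter-channel correlation beyond the blink topography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from eegstress.signal_io import EEGRecording

#: 10-20 labels for the 32-electrode montage, frontal to occipital.
CHANNEL_LABELS_32 = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "O2",
)

#: Scalp row (front-to-back) of each electrode prefix, for blink decay.
_ROW_BY_PREFIX = {"Fp": 0, "F": 1, "FC": 2, "T": 3, "C": 3, "CP": 4, "P": 5, "PO": 6, "O": 7}

POSTERIOR_PREFIXES = ("P", "PO", "O")

BLINK_DURATION_S = 0.3
BLINK_ROW_DECAY = 2.5  # e-folding of blink amplitude per scalp row; blinks spread broadly over frontal sites
BACKGROUND_RMS_UV = 10.0


def _electrode_row(label: str) -> int:
    for prefix in ("Fp", "FC", "CP", "PO", "F", "T", "C", "P", "O"):
        if label.startswith(prefix):
            return _ROW_BY_PREFIX[prefix]
    return _ROW_BY_PREFIX["C"]


@dataclass(frozen=True)
class SynthConfig:
    """Generation settings; defaults emulate the target recordings."""

    n_channels: int = 32
    rate: float = 1000.0
    duration_s: float = 4.0
    blink_rate: float = 12.0  # blinks per minute
    blink_amplitude: float = 100.0  # uV at the frontal electrodes
    background_slope: float = 1.0  # 1/f^slope background power
    class_effect: float = 0.5  # band-power shift, as a fraction of background RMS
    n_subjects: int = 2
    files_per_subject: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration_s <= 0:
            raise ValueError("rate and duration must be positive")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be non-negative")
        if self.files_per_subject < 2:
            raise ValueError("need at least 2 files per subject")
        if not (1 <= self.n_channels <= len(CHANNEL_LABELS_32)):
            raise ValueError(f"n_channels must be in [1, {len(CHANNEL_LABELS_32)}]")


def blink_template(rate: float, amplitude: float) -> np.ndarray:
    """300 ms biphasic raised-cosine pulse, peak value = amplitude."""
    n = max(int(round(BLINK_DURATION_S * rate)), 4)
    u = np.arange(n) / n
    w = np.hanning(n) * np.sin(2.0 * np.pi * u)
    return amplitude * w / np.max(np.abs(w))


def _pink_background(rng: np.random.Generator, n_channels: int, n_samples: int, slope: float) -> np.ndarray:
    """Per-channel noise with power spectrum ~ 1/f^slope, unit RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    gain = np.ones_like(f)
    gain[1:] = f[1:] ** (-slope / 2.0)
    gain[0] = 0.0
    shaped = np.fft.irfft(spectrum * gain, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    return shaped / rms


def _band_noise(rng: np.random.Generator, n_samples: int, rate: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    nyq = rate / 2.0
    sos = sp_signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / np.sqrt(np.mean(x**2))


def generate_recording(
    cfg: SynthConfig,
    label: int = 0,
    seed: int | None = None,
    subject_id: str = "s00",
    file_id: str = "f00",
) -> tuple[EEGRecording, list[tuple[int, int]]]:
    """One labeled recording plus the exact blink sample windows.

    ``label`` is 1 for "stressed" (beta-band boost on posterior
    channels) and 0 for "calm" (alpha-band boost). Same seed, same
    output, bit for bit.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels = list(CHANNEL_LABELS_32[: cfg.n_channels])
    n_samples = int(round(cfg.duration_s * cfg.rate))
    data = BACKGROUND_RMS_UV * _pink_background(rng, cfg.n_channels, n_samples, cfg.background_slope)

    # class-dependent band-power shift on posterior channels
    band = (13.0, 30.0) if label == 1 else (8.0, 13.0)
    amp = cfg.class_effect * BACKGROUND_RMS_UV
    for i, lab in enumerate(labels):
        if lab.startswith(POSTERIOR_PREFIXES):
            data[i] += amp * _band_noise(rng, n_samples, cfg.rate, band)

    # blinks at Poisson times, frontal-dominant topography
    blink_truth: list[tuple[int, int]] = []
    template = blink_template(cfg.rate, cfg.blink_amplitude)
    n_blinks = rng.poisson(cfg.blink_rate / 60.0 * cfg.duration_s)
    profile = np.exp(-np.array([_electrode_row(lab) for lab in labels]) / BLINK_ROW_DECAY)
    if n_blinks > 0 and n_samples > template.size:
        starts = np.sort(rng.integers(0, n_samples - template.size, size=n_blinks))
        for s in starts:
            data[:, s : s + template.size] += np.outer(profile, template)
            blink_truth.append((int(s), int(s + template.size)))

    rec = EEGRecording(
        data=data,
        rate=cfg.rate,
        channel_labels=labels,
        subject_id=subject_id,
        file_id=file_id,
    )
    return rec, blink_truth


def generate_dataset(cfg: SynthConfig):
    """All files for all subjects, with balanced alternating labels.

    Yields ``(recording, label, blink_truth)``; file seeds derive
    deterministically from ``cfg.seed``.
    """
    out = []
    for si in range(cfg.n_subjects):
        for fi in range(cfg.files_per_subject):
            label = fi % 2
            seed = (cfg.seed * 100003 + si * 1009 + fi) % (2**31)
            rec, truth = generate_recording(
                cfg,
                label=label,
                seed=seed,
                subject_id=f"s{si:02d}",
                file_id=f"s{si:02d}_f{fi:02d}",
            )
            out.append((rec, label, truth))
    return out


def generate_labeled_dataset(
    n_per_class: int,
    n_features: int,
    informative: list[int],
    effect_size: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Gaussian feature matrix with a planted class effect.

    Informative columns are N(0,1) for class 0 and N(d,1) for class 1;
    all other columns are N(0,1) for both. Labels are exactly
    balanced. This is the test bed for wrapper feature selection and
    kernel search.
    """
    if n_per_class < 4:
        raise ValueError("need at least 4 samples per class")
    informative = sorted(set(int(i) for i in informative))
    if informative and (informative[0] < 0 or informative[-1] >= n_features):
        raise ValueError("informative indices out of range")
    if effect_size < 0:
        raise ValueError("effect size must be non-negative")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    y = np.zeros(n, dtype=int)
    y[n_per_class:] = 1
    X[n_per_class:, informative] += effect_size
    perm = rng.permutation(n)
    return X[perm], y[perm], informative
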