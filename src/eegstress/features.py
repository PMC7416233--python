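"""DCT-II spectrum and the fixed 24-feature bank.

One feature vector is computed per file, on a designated analysis
signal (by default the mean of the occipital channels of the cleaned
recording). Half the features are time-domain statistics, half are
computed on the orthonormal DCT-II spectrum ``A(p)``:

    A(p) = alpha(p) * sum_{n=0}^{N-1} x(n) cos(pi (2n+1) p / (2N)),
    alpha(0) = sqrt(1/N), alpha(p != 0) = sqrt(2/N),

so that Parseval holds exactly (sum x^2 == sum A^2). ``A(0)`` is the DC
coefficient and carries the (scaled) signal mean. DCT bin ``p``
corresponds to frequency ``p * rate / (2N)`` Hz.

Degenerate inputs (zero variance, zero spectral energy) set the
affected feature to 0 and log a warning instead of raising — constant
or silent channels should never abort a batch run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical feature order. Fixed across runs and platforms; feature
#: CSVs and selection masks index into this list.
FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "std",
    "variance",
    "mean_abs_deviation",
    "skewness",
    "kurtosis",
    "rms",
    "peak_to_peak",
    "short_time_energy",
    "waveform_length",
    "zero_crossing_rate",
    "wilson_amplitude",
    "snr",
    "dominant_frequency",
    "spectral_centroid",
    "spectral_flux",
    "spectral_rolloff",
    "band_power_delta",
    "band_power_theta",
    "band_power_alpha",
    "band_power_beta",
    "dct_dc",
    "cross_convolution_peak",
)

N_FEATURES = len(FEATURE_NAMES)

#: EEG band edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

STE_FRAME = 256  # samples per short-time-energy frame (50% overlap)
ROLLOFF_FRACTION = 0.85
SNR_TOP_BINS = 3
MIN_SAMPLES = 32


@dataclass
class FeatureVector:
    """Ordered, named 24-element feature vector for one file."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    subject_id: str = ""
    file_id: str = ""
    label: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(f"expected {len(self.names)} values, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature value")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def dct_type2(x: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II of a real vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input must be a non-empty 1-D vector")
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    return sp_fft.dct(x, type=2, norm="ortho")


def idct_type2(A: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct_type2` (orthonormal DCT-III)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 1 or A.size == 0:
        raise ValueError("input must be a non-empty 1-D vector")
    return sp_fft.idct(A, type=2, norm="ortho")


def dct_bin_frequencies(n: int, rate: float) -> np.ndarray:
    """Frequency in Hz of each DCT bin: f(p) = p * rate / (2N)."""
    return np.arange(n) * rate / (2.0 * n)


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    # a zero sample inherits the preceding sign so a touch is not two crossings
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return int(np.sum(s[:-1] * s[1:] < 0))


def _short_time_energy(x: np.ndarray, frame: int = STE_FRAME) -> float:
    if x.size <= frame:
        return float(np.sum(x**2))
    hop = frame // 2
    starts = range(0, x.size - frame + 1, hop)
    return float(np.mean([np.sum(x[s : s + frame] ** 2) for s in starts]))


def _spectral_flux(x: np.ndarray) -> float:
    """Euclidean distance between the DCT magnitude spectra of the two
    half-signals; a crude non-stationarity index."""
    h = x.size // 2
    a = np.abs(dct_type2(x[:h]))
    b = np.abs(dct_type2(x[h : 2 * h]))
    return float(np.linalg.norm(a - b))


def _cross_convolution_peak(x: np.ndarray) -> float:
    """Peak of the convolution of two half-length, half-overlapping
    segments, normalized by the total signal energy."""
    h = x.size // 2
    a = x[:h]
    b = x[h // 2 : h // 2 + h]
    energy = float(np.sum(x**2))
    if energy <= 0.0:
        logger.warning("cross_convolution_peak undefined on zero-energy input; returning 0")
        return 0.0
    return float(np.max(np.convolve(a, b)) / energy)


def extract_features(x: np.ndarray, rate: float) -> FeatureVector:
    """Compute the canonical 24 features of one signal.

    Deterministic for fixed input. Requires at least 32 samples so the
    split-half spectral features are meaningful.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be 1-D")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {x.size}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")

    n = x.size
    duration = n / rate
    std = float(np.std(x))
    diffs = np.abs(np.diff(x))

    if std > 0.0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))  # excess kurtosis; 0 for a Gaussian
    else:
        logger.warning("zero-variance input: skewness/kurtosis set to 0")
        skew = 0.0
        kurt = 0.0

    A = dct_type2(x)
    mag = np.abs(A)
    freqs = dct_bin_frequencies(n, rate)
    ac_power = A[1:] ** 2
    ac_mag = mag[1:]
    ac_freqs = freqs[1:]

    # SNR: power concentrated in the 3 largest-magnitude bins vs the rest
    order = np.argsort(mag)[::-1]
    top = float(np.sum(mag[order[:SNR_TOP_BINS]] ** 2))
    rest = float(np.sum(mag[order[SNR_TOP_BINS:]] ** 2))
    if rest > 0.0:
        snr = 10.0 * np.log10(top / rest) if top > 0.0 else 0.0
    else:
        logger.warning("SNR undefined (no residual spectral power); returning 0")
        snr = 0.0

    total_ac_mag = float(np.sum(ac_mag))
    total_ac_pow = float(np.sum(ac_power))
    if total_ac_pow > 0.0:
        dominant = float(ac_freqs[int(np.argmax(ac_mag))])
        centroid = float(np.sum(ac_freqs * ac_mag) / total_ac_mag)
        cum = np.cumsum(ac_power)
        idx = min(int(np.searchsorted(cum, ROLLOFF_FRACTION * total_ac_pow)), ac_freqs.size - 1)
        rolloff = float(ac_freqs[idx])
    else:
        logger.warning("flat spectrum: dominant/centroid/rolloff set to 0")
        dominant = centroid = rolloff = 0.0

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(np.mean(A[sel] ** 2)) if sel.any() else 0.0

    values = np.array(
        [
            np.mean(x),
            np.median(x),
            std,
            np.var(x),
            np.mean(np.abs(x - np.mean(x))),
            skew,
            kurt,
            np.sqrt(np.mean(x**2)),
            np.ptp(x),
            _short_time_energy(x),
            float(np.sum(diffs)),
            _zero_crossings(x) / duration,
            float(np.sum(diffs > 0.5 * std)) if std > 0.0 else 0.0,
            snr,
            dominant,
            centroid,
            _spectral_flux(x),
            rolloff,
            band_power(*BANDS["delta"]),
            band_power(*BANDS["theta"]),
            band_power(*BANDS["alpha"]),
            band_power(*BANDS["beta"]),
            A[0],
            _cross_convolution_peak(x),
        ]
    )
    return FeatureVector(values=values)


DEFAULT_ANALYSIS_CHANNELS = ("O1", "O2", "Oz")


def analysis_signal(rec, channels: list[str] | None = None) -> np.ndarray:
    """Collapse a recording to the single series features are computed on.

    Default: mean of whichever occipital channels (O1/O2/Oz) are
    present; falls back to the mean of all channels if none are.
    """
    if channels is None:
        channels = [c for c in DEFAULT_ANALYSIS_CHANNELS if c in rec.channel_labels]
        if not channels:
            return rec.data.mean(axis=0)
    from eegstress.signal_io import select_channels

    return select_channels(rec, list(channels)).data.mean(axis=0)


def features_from_recording(rec, channels: list[str] | None = None) -> FeatureVector:
    """Per-file feature vector from a (cleaned) recording."""
    fv = extract_features(analysis_signal(rec, channels), rec.rate)
    fv.subject_id = rec.subject_id
    fv.file_id = rec.file_id
    return fv


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a tidy table (one row per file)."""
    rows = []
    for fv in vectors:
        row = fv.as_dict()
        row["subject_id"] = fv.subject_id
        row["file_id"] = fv.file_id
        row["label"] = fv.label
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["subject_id", "file_id", "label"])
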