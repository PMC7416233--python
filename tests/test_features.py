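"""DCT-II oracle equivalence and the 24-feature bank."""

import logging
import math

import numpy as np
import pytest

from eegstress.features import (
    BANDS,
    FEATURE_NAMES,
    ROLLOFF_FRACTION,
    SNR_TOP_BINS,
    STE_FRAME,
    dct_bin_frequencies,
    dct_type2,
    extract_features,
    idct_type2,
)


def brute_force_dct2(x):
    """Direct double-loop evaluation of the orthonormal DCT-II."""
    n = len(x)
    A = np.zeros(n)
    for p in range(n):
        alpha = math.sqrt(1.0 / n) if p == 0 else math.sqrt(2.0 / n)
        A[p] = alpha * sum(x[i] * math.cos(math.pi * (2 * i + 1) * p / (2 * n)) for i in range(n))
    return A


def brute_force_idct2(A):
    """Direct double-loop evaluation of the synthesis (inverse) sum."""
    n = len(A)
    x = np.zeros(n)
    for i in range(n):
        x[i] = sum(
            (math.sqrt(1.0 / n) if p == 0 else math.sqrt(2.0 / n))
            * A[p]
            * math.cos(math.pi * (2 * i + 1) * p / (2 * n))
            for p in range(n)
        )
    return x


@pytest.mark.parametrize("n", [1, 4, 8, 16, 64])
def test_dct_matches_brute_force(n):
    rng = np.random.default_rng(n)
    x = rng.normal(size=n)
    np.testing.assert_allclose(dct_type2(x), brute_force_dct2(x), atol=1e-10)
    A = rng.normal(size=n)
    np.testing.assert_allclose(idct_type2(A), brute_force_idct2(A), atol=1e-10)


def test_dct_constant_signal_is_dc_only():
    np.testing.assert_allclose(dct_type2([1.0, 1.0, 1.0, 1.0]), [2.0, 0.0, 0.0, 0.0], atol=1e-14)
    np.testing.assert_allclose(idct_type2([2.0, 0.0, 0.0, 0.0]), [1.0, 1.0, 1.0, 1.0], atol=1e-14)


def test_dct_round_trip_and_parseval(rng):
    for n in (8, 16, 257):
        x = rng.normal(size=n)
        A = dct_type2(x)
        np.testing.assert_allclose(idct_type2(A), x, atol=1e-10)
        assert abs(np.sum(x**2) - np.sum(A**2)) < 1e-9


def test_dct_rejects_empty_and_non_finite():
    with pytest.raises(ValueError):
        dct_type2([])
    with pytest.raises(ValueError):
        dct_type2([np.nan, 1.0])
    with pytest.raises(ValueError):
        idct_type2([])


def test_feature_list_is_canonical():
    assert len(FEATURE_NAMES) == 24
    assert len(set(FEATURE_NAMES)) == 24


def test_constant_signal_features_follow_degenerate_rules(caplog):
    x = np.ones(64)
    with caplog.at_level(logging.WARNING):
        fv = extract_features(x, rate=100.0)
    assert fv["mean"] == 1.0
    assert fv["variance"] == 0.0
    assert fv["waveform_length"] == 0.0
    assert fv["zero_crossing_rate"] == 0.0
    assert fv["skewness"] == 0.0
    assert fv["kurtosis"] == 0.0
    assert fv["wilson_amplitude"] == 0.0
    assert np.isfinite(fv.values).all()


def test_sinusoid_features_match_analytic_values():
    rate = 1000.0
    t = np.arange(1000) / rate
    x = np.sin(2 * np.pi * 10.0 * t)
    fv = extract_features(x, rate)
    bin_width = rate / (2 * len(x))
    assert abs(fv["dominant_frequency"] - 10.0) <= bin_width
    assert abs(fv["mean"]) < 1e-10
    assert abs(fv["zero_crossing_rate"] - 20.0) <= 1.0


def naive_features(x, rate):
    """Straight-line per-feature reimplementation (independent oracle)."""
    n = len(x)
    out = {}
    mu = sum(x) / n
    out["mean"] = mu
    out["median"] = float(np.sort(x)[n // 2]) if n % 2 else float(np.mean(np.sort(x)[n // 2 - 1 : n // 2 + 1]))
    var = sum((v - mu) ** 2 for v in x) / n
    sd = math.sqrt(var)
    out["std"] = sd
    out["variance"] = var
    out["mean_abs_deviation"] = sum(abs(v - mu) for v in x) / n
    out["skewness"] = (sum((v - mu) ** 3 for v in x) / n) / sd**3
    out["kurtosis"] = (sum((v - mu) ** 4 for v in x) / n) / sd**4 - 3.0
    out["rms"] = math.sqrt(sum(v**2 for v in x) / n)
    out["peak_to_peak"] = max(x) - min(x)
    if n <= STE_FRAME:
        out["short_time_energy"] = sum(v**2 for v in x)
    else:
        frames = [
            sum(v**2 for v in x[s : s + STE_FRAME])
            for s in range(0, n - STE_FRAME + 1, STE_FRAME // 2)
        ]
        out["short_time_energy"] = sum(frames) / len(frames)
    out["waveform_length"] = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    crossings = sum(1 for i in range(n - 1) if x[i] * x[i + 1] < 0)
    out["zero_crossing_rate"] = crossings / (n / rate)
    out["wilson_amplitude"] = sum(1 for i in range(n - 1) if abs(x[i + 1] - x[i]) > 0.5 * sd)
    A = brute_force_dct2(x)
    mag = np.abs(A)
    order = np.argsort(mag)[::-1]
    top = sum(mag[p] ** 2 for p in order[:SNR_TOP_BINS])
    rest = sum(mag[p] ** 2 for p in order[SNR_TOP_BINS:])
    out["snr"] = 10.0 * math.log10(top / rest)
    freqs = [p * rate / (2 * n) for p in range(n)]
    ac = list(range(1, n))
    out["dominant_frequency"] = freqs[max(ac, key=lambda p: mag[p])]
    out["spectral_centroid"] = sum(freqs[p] * mag[p] for p in ac) / sum(mag[p] for p in ac)
    h = n // 2
    a1 = np.abs(brute_force_dct2(x[:h]))
    a2 = np.abs(brute_force_dct2(x[h : 2 * h]))
    out["spectral_flux"] = math.sqrt(sum((a1[i] - a2[i]) ** 2 for i in range(h)))
    total = sum(A[p] ** 2 for p in ac)
    cum = 0.0
    for p in ac:
        cum += A[p] ** 2
        if cum >= ROLLOFF_FRACTION * total:
            out["spectral_rolloff"] = freqs[p]
            break
    for band, (lo, hi) in BANDS.items():
        sel = [p for p in range(n) if lo <= freqs[p] < hi]
        out[f"band_power_{band}"] = sum(A[p] ** 2 for p in sel) / len(sel) if sel else 0.0
    out["dct_dc"] = A[0]
    seg_a = x[:h]
    seg_b = x[h // 2 : h // 2 + h]
    conv = np.convolve(seg_a, seg_b)
    out["cross_convolution_peak"] = max(conv) / sum(v**2 for v in x)
    return out


def test_every_feature_matches_naive_oracle():
    rng = np.random.default_rng(99)
    x = rng.standard_normal(512)
    fv = extract_features(x, rate=256.0)
    oracle = naive_features(list(x), 256.0)
    for name in FEATURE_NAMES:
        assert abs(fv[name] - oracle[name]) < 1e-9, name


def test_scale_consistency(rng):
    x = rng.standard_normal(300)
    c = 3.7
    f1 = extract_features(x, 100.0)
    f2 = extract_features(c * x, 100.0)
    for name in ("mean", "median", "std", "mean_abs_deviation", "waveform_length"):
        assert abs(f2[name] - c * f1[name]) < 1e-8 * max(1.0, abs(f1[name])), name
    for name in ("skewness", "kurtosis", "zero_crossing_rate"):
        assert abs(f2[name] - f1[name]) < 1e-8, name


def test_extract_features_input_validation():
    with pytest.raises(ValueError):
        extract_features(np.ones(10), 100.0)  # too short
    with pytest.raises(ValueError):
        extract_features(np.ones(64), 0.0)
    with pytest.raises(ValueError):
        extract_features(np.full(64, np.nan), 100.0)
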