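"""Shared fixtures: seeded RNGs and a minimal synthetic EDF writer."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def write_minimal_edf(path, data, rate, labels, samples_per_record=None):
    """Write a minimal single-record synthetic EDF file for round-trip tests.

    16-bit quantization over the per-channel physical range; physical
    dimension is uV. ``samples_per_record`` may be given per channel to
    fabricate a (normally invalid) multi-rate file.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if samples_per_record is None:
        samples_per_record = [n_samp] * n_ch
    dur = n_samp / rate

    def field(vals, w):
        return b"".join(str(v).encode().ljust(w) for v in vals)

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    pmins = np.where(pmaxs - pmins < 1e-9, pmins - 1.0, pmins)
    header = b"0".ljust(8)
    header += b"X X X X".ljust(80)
    header += b"Startdate X".ljust(80)
    header += b"01.01.20" + b"00.00.00"
    header += str(256 + n_ch * 256).encode().ljust(8)
    header += b"".ljust(44)
    header += b"1".ljust(8)  # one data record
    header += ("%g" % dur).encode().ljust(8)
    header += str(n_ch).encode().ljust(4)
    header += field(labels, 16)
    header += field([""] * n_ch, 80)
    header += field(["uV"] * n_ch, 8)
    header += field(["%g" % v for v in pmins], 8)
    header += field(["%g" % v for v in pmaxs], 8)
    header += field([-32768] * n_ch, 8)
    header += field([32767] * n_ch, 8)
    header += field([""] * n_ch, 80)
    header += field(samples_per_record, 8)
    header += field([""] * n_ch, 32)
    with open(path, "wb") as f:
        f.write(header)
        for ch in range(n_ch):
            span = pmaxs[ch] - pmins[ch]
            scaled = np.round((data[ch] - pmins[ch]) / span * 65535.0 - 32768.0)
            f.write(scaled.astype("<i2").tobytes())
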