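"""Reading and writing multichannel EEG recordings.

In memory a recording is always channels x samples (microvolts). On disk
the CSV layout is transposed — one row per time point, one column per
channel, with a header row of 10-20 electrode labels — because that is
the layout flat EEG exports normally use. Sample indices are 0-based and
sample ``i`` occurs at ``i / rate`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DEFAULT_RATE = 1000.0


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    rate
        Sampling frequency in Hz.
    channel_labels
        Ordered electrode names (10-20 system), one per row of ``data``.
    subject_id, file_id
        Free-form identifiers used by the pipeline bookkeeping.
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    subject_id: str = ""
    file_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError(f"data must have at least one channel and one sample, got {self.data.shape}")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        """Time of each sample in seconds."""
        return np.arange(self.n_samples) / self.rate


def read_recording_csv(
    path,
    rate: float = DEFAULT_RATE,
    subject_id: str = "",
    file_id: str = "",
) -> EEGRecording:
    """Read a recording from CSV (header = channel labels, one row per sample).

    The sampling rate is not stored in the CSV; pass it explicitly
    (default 1000 Hz, the rate of typical research-grade amplifiers).
    """
    try:
        df = pd.read_csv(path, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV (ragged rows?): {path}: {exc}") from None
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"empty recording CSV: {path}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"ragged or missing cell at data row {row} in {path}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # numpy's parser round-trips "%.17g" output exactly
            values[:, j] = df[col].to_numpy(dtype=str).astype(np.float64)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad.isna().idxmax())
            raise ValueError(
                f"non-numeric cell at row {row}, column {col!r} in {path}"
            ) from None
    return EEGRecording(
        data=values.T,
        rate=rate,
        channel_labels=[str(c) for c in df.columns],
        subject_id=subject_id,
        file_id=file_id,
    )


def write_recording_csv(rec: EEGRecording, path) -> None:
    """Write a recording as samples x channels CSV with a label header.

    Values are written with full ``repr`` precision so a read-back
    reproduces them bit-exactly.
    """
    np.savetxt(
        path,
        rec.data.T,
        delimiter=",",
        header=",".join(rec.channel_labels),
        comments="",
        fmt="%.17g",  # shortest form guaranteeing exact float64 round-trip
    )


def _edf_samples_per_record(path) -> list[int]:
    """Samples-per-record for every signal, straight from the EDF header."""
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise ValueError(f"truncated EDF header: {path}")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError:
            raise ValueError(f"corrupt EDF header (signal count field): {path}") from None
        f.seek(256 + ns * 216)
        raw = f.read(ns * 8)
        if len(raw) < ns * 8:
            raise ValueError(f"truncated EDF signal header: {path}")
        return [int(raw[i * 8 : (i + 1) * 8].decode("ascii").strip()) for i in range(ns)]


def read_recording_edf(path, subject_id: str = "", file_id: str = "") -> EEGRecording:
    """Read a recording from an EDF(+) file; annotations are ignored.

    All signals must share one sampling rate. Values are returned in
    microvolts (converted from the physical dimension in the header).
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    n_samples = _edf_samples_per_record(path)
    if len(set(n_samples)) > 1:
        raise ValueError("heterogeneous sampling rates unsupported")
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # corrupt payload past our header check
        raise ValueError(f"cannot read EDF file {path}: {exc}") from None
    return EEGRecording(
        data=raw.get_data(units="uV"),
        rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        file_id=file_id,
    )


def select_channels(rec: EEGRecording, labels: list[str]) -> EEGRecording:
    """Restrict a recording to the requested channels, in the requested order."""
    index = {name: i for i, name in enumerate(rec.channel_labels)}
    missing = [lab for lab in labels if lab not in index]
    if missing:
        raise KeyError(f"unknown channel label(s): {missing}")
    rows = [index[lab] for lab in labels]
    return replace(rec, data=rec.data[rows], channel_labels=list(labels))
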