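"""Audio and annotation I/O.

Waveforms are mono float arrays at a known sampling rate (nominally 250 kHz,
high enough to resolve the 1–125 kHz analysis band).  Annotations are simple
CSV tables of ``onset,offset,label`` rows in seconds; the label vocabulary is
``USV`` (ultrasonic vocalization), ``AC`` (alarm call, excluded from scoring)
and ``noise``.  Amplitudes are kept as stored — no peak normalization is
applied; scale robustness is the training augmentation's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "Waveform",
    "LabelTable",
    "LABEL_VOCABULARY",
    "read_wav",
    "write_wav",
    "read_labels",
    "write_labels",
    "merge_usv_rows",
]

LABEL_VOCABULARY = ("USV", "AC", "noise")

#: Columns written for detection tables (the truth schema plus scores/bounds).
DETECTION_COLUMNS = ("onset", "offset", "label", "score", "freq_low_hz", "freq_high_hz")


@dataclass
class Waveform:
    """Mono audio samples with their sampling rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise ValueError("Waveform must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if int(self.rate) <= 0:
            raise ValueError(f"Sampling rate must be positive, got {self.rate}")
        self.rate = int(self.rate)

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.samples.size / self.rate


@dataclass
class LabelTable:
    """Sorted table of (onset, offset, label) annotation rows in seconds."""

    rows: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows)
        required = {"onset", "offset", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"Label table is missing columns: {sorted(missing)}")
        if len(df):
            bad = df[~df["label"].isin(LABEL_VOCABULARY)]
            if len(bad):
                raise ValueError(
                    f"Unknown labels {sorted(bad['label'].unique())}; "
                    f"expected one of {LABEL_VOCABULARY}"
                )
            inverted = df[df["onset"] >= df["offset"]]
            if len(inverted):
                rows = ", ".join(
                    f"({r.onset:g}, {r.offset:g}, {r.label})"
                    for r in inverted.itertuples()
                )
                raise ValueError(f"Rows with onset >= offset: {rows}")
        df = df.sort_values("onset", kind="stable").reset_index(drop=True)
        self.rows = df[["onset", "offset", "label"]].astype(
            {"onset": float, "offset": float, "label": str}
        )

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        if len(self) == 0:
            return True
        return (
            np.allclose(self.rows["onset"], other.rows["onset"], atol=1e-6)
            and np.allclose(self.rows["offset"], other.rows["offset"], atol=1e-6)
            and (self.rows["label"] == other.rows["label"]).all()
        )

    def usv_intervals(self) -> np.ndarray:
        """(n, 2) array of USV [onset, offset] rows; AC/noise rows excluded."""
        usv = self.rows[self.rows["label"] == "USV"]
        return usv[["onset", "offset"]].to_numpy(dtype=float).reshape(-1, 2)


def merge_usv_rows(table: LabelTable) -> np.ndarray:
    """Union of overlapping/abutting USV rows as an (n, 2) interval array.

    Manual annotations may abut or overlap; downstream frame labeling treats
    them as a single span of vocal activity.
    """
    spans = table.usv_intervals()
    if len(spans) == 0:
        return spans
    merged: list[list[float]] = [list(spans[0])]
    for onset, offset in spans[1:]:
        if onset <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], offset)
        else:
            merged.append([onset, offset])
    return np.asarray(merged, dtype=float)


def read_wav(path, target_rate: int = 250_000) -> Waveform:
    """Read a WAV file as mono float samples at ``target_rate``.

    Integer PCM is rescaled to [-1, 1) by the type's full-scale value; float
    files are used as stored.  Stereo input is reduced to mono by channel
    averaging.  Resampling is polyphase (:func:`scipy.signal.resample_poly`).
    """
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"{path}: zero-length audio")
    if data.ndim == 2:
        data = data.astype(np.float64).mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(np.float64) / float(-info.min)
    else:
        data = data.astype(np.float64)
    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        data = resample_poly(data, target_rate // g, rate // g)
    return Waveform(samples=data, rate=int(target_rate))


def write_wav(waveform: Waveform, path) -> None:
    """Write a waveform as 32-bit float WAV (lossless for our pipeline)."""
    wavfile.write(path, waveform.rate, waveform.samples.astype(np.float32))


def read_labels(path, source: str | None = None) -> LabelTable:
    """Read an annotation CSV with header ``onset,offset,label``."""
    df = pd.read_csv(path)
    return LabelTable(rows=df, source=source if source is not None else str(path))


def write_labels(table: LabelTable, path) -> None:
    """Write an annotation table; onsets/offsets keep microsecond precision."""
    table.rows.to_csv(path, index=False, float_format="%.6f")
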