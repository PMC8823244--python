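"""From probability tracks and frequency masks to USV detections.

A detection is a maximal run of frames whose P(USV) meets the threshold;
runs separated by less than ``merge_gap`` are merged and runs shorter than
``min_dur`` are dropped (both default well below the shortest typical USV).
Frequency boundaries come from the frequency mask: the lowest/highest Mel
band whose mean mask over the detection reaches ``mask_threshold``, mapped
to Hz through the filterbank band edges (lower edge for the low bound, upper
edge for the high bound — conservative given the Mel scale's coarse high
frequencies).

Denoising is the elementwise product spectrogram * mask * track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import MelSpectrogram

__all__ = [
    "PostprocessConfig",
    "UsvInterval",
    "track_to_detections",
    "freq_bounds",
    "denoise",
    "detections_to_frame",
    "write_detections",
    "read_detections",
]


@dataclass
class PostprocessConfig:
    threshold: float = 0.5
    min_dur: float = 0.005     # s; below the shortest reported USV durations
    merge_gap: float = 0.010   # s
    mask_threshold: float = 0.5


@dataclass
class UsvInterval:
    """A detected USV with its score and (optional) frequency bounds."""

    onset: float
    offset: float
    score: float
    freq_low_hz: float | None = None
    freq_high_hz: float | None = None

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"Interval onset {self.onset} must precede offset {self.offset}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"Score must be in [0, 1], got {self.score}")
        if (
            self.freq_low_hz is not None
            and self.freq_high_hz is not None
            and self.freq_low_hz > self.freq_high_hz
        ):
            raise ValueError("freq_low_hz must not exceed freq_high_hz")


def track_to_detections(
    track: np.ndarray,
    frame_rate: float,
    threshold: float = 0.5,
    min_dur: float = 0.0,
    merge_gap: float = 0.0,
) -> list[UsvInterval]:
    """Threshold a per-frame P(USV) track into detected intervals.

    Frame t spans [t, t+1)/frame_rate.  Runs of frames with P >= threshold
    become intervals; intervals separated by less than ``merge_gap`` seconds
    are merged, then intervals shorter than ``min_dur`` are dropped.  Scores
    are the mean track value over the interval's frames.
    """
    track = np.asarray(track, dtype=np.float64)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"Threshold must be in (0, 1), got {threshold}")
    active = track >= threshold
    if not active.any():
        return []
    padded = np.concatenate([[False], active, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]  # frame runs [start, stop)
    runs = list(zip(starts.tolist(), stops.tolist()))
    if merge_gap > 0:
        merged = [list(runs[0])]
        for start, stop in runs[1:]:
            if (start - merged[-1][1]) / frame_rate < merge_gap:
                merged[-1][1] = stop
            else:
                merged.append([start, stop])
        runs = [tuple(r) for r in merged]
    detections = []
    for start, stop in runs:
        onset, offset = start / frame_rate, stop / frame_rate
        if offset - onset < min_dur:
            continue
        detections.append(
            UsvInterval(
                onset=onset,
                offset=offset,
                score=float(np.clip(track[start:stop].mean(), 0.0, 1.0)),
            )
        )
    return detections


def freq_bounds(
    mask: np.ndarray,
    interval: UsvInterval,
    spec: MelSpectrogram,
    mask_threshold: float = 0.5,
) -> tuple[float | None, float | None]:
    """Frequency bounds of a detection from the (n_bands, n_frames) mask.

    A band is active when its mean mask value over the detection's frames
    reaches ``mask_threshold``.  Returns (None, None) when no band is active
    (the detection is kept, just without spectral bounds).
    """
    start = int(np.floor(interval.onset * spec.frame_rate))
    stop = max(start + 1, int(np.ceil(interval.offset * spec.frame_rate)))
    stop = min(stop, mask.shape[1])
    start = min(start, stop - 1)
    band_mean = np.asarray(mask, dtype=np.float64)[:, start:stop].mean(axis=1)
    active = np.flatnonzero(band_mean >= mask_threshold)
    if active.size == 0:
        return None, None
    low, _ = spec.band_bounds_hz(int(active[0]))
    _, high = spec.band_bounds_hz(int(active[-1]))
    return low, high


def denoise(
    spectrogram: np.ndarray, mask: np.ndarray, track: np.ndarray
) -> np.ndarray:
    """Cleaned spectrogram: ``spectrogram * mask * track`` elementwise.

    ``spectrogram`` and ``mask`` are (n_bands, n_frames); ``track`` is
    per-frame and broadcast across bands.  No other transformation.
    """
    spectrogram = np.asarray(spectrogram, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    track = np.asarray(track, dtype=np.float64)
    if spectrogram.shape != mask.shape:
        raise ValueError(
            f"Spectrogram shape {spectrogram.shape} != mask shape {mask.shape}"
        )
    if track.shape != (spectrogram.shape[1],):
        raise ValueError(
            f"Track length {track.shape} does not match {spectrogram.shape[1]} frames"
        )
    return spectrogram * mask * track[None, :]


def detections_to_frame(detections: list[UsvInterval]) -> pd.DataFrame:
    """Detections as a DataFrame in the annotation CSV schema plus scores."""
    return pd.DataFrame(
        {
            "onset": [d.onset for d in detections],
            "offset": [d.offset for d in detections],
            "label": ["USV"] * len(detections),
            "score": [d.score for d in detections],
            "freq_low_hz": [d.freq_low_hz for d in detections],
            "freq_high_hz": [d.freq_high_hz for d in detections],
        }
    )


def write_detections(detections: list[UsvInterval], path) -> None:
    detections_to_frame(detections).to_csv(path, index=False, float_format="%.6f")


def read_detections(path) -> list[UsvInterval]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        out.append(
            UsvInterval(
                onset=float(row.onset),
                offset=float(row.offset),
                score=float(getattr(row, "score", 1.0)),
                freq_low_hz=None if pd.isna(getattr(row, "freq_low_hz", np.nan)) else float(row.freq_low_hz),
                freq_high_hz=None if pd.isna(getattr(row, "freq_high_hz", np.nan)) else float(row.freq_high_hz),
            )
        )
    return out
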