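"""Mel-spectrogram features, context windows and frame-level labels.

The detector works on a log-Mel energy image: 124 bands spanning 1–125 kHz on
the Mel scale, at ~332 frames per second (~3 ms per time step) for 250 kHz
input.  Each frame is classified in the context of its 25 preceding and 25
following frames, i.e. a 124 x 51 patch.

Frame t owns the half-open time span [t*hop, (t+1)*hop)/rate; spans tile the
recording without overlap, so frame labels and detection boundaries round-trip
to within one frame period.  The analysis window (1024 samples, Hann) is
longer than the hop and starts at t*hop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .audio_io import LabelTable, Waveform, merge_usv_rows

__all__ = [
    "FeatureConfig",
    "MelSpectrogram",
    "FrameLabels",
    "mel_filterbank",
    "hz_to_mel",
    "mel_to_hz",
    "melspec",
    "context_windows",
    "labels_to_frames",
]


def hz_to_mel(f):
    """HTK Mel scale: mel = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@dataclass
class FeatureConfig:
    """Feature-extraction parameters.

    ``frame_rate`` is nominal: the hop is ``round(rate / frame_rate)`` samples
    (753 at 250 kHz) so the realized rate is within a fraction of a frame of
    332/s.  ``n_fft`` is larger than ``win_length`` (zero-padded FFT) so the
    narrow low-frequency Mel bands retain spectral support.
    ``log_floor`` is the additive floor on band energies before the natural
    log; silence maps exactly to ``log(log_floor)``.
    """

    n_bands: int = 124
    fmin_hz: float = 1_000.0
    fmax_hz: float = 125_000.0
    frame_rate: float = 332.0
    win_length: int = 1024
    n_fft: int = 4096
    log_floor: float = 1e-10

    @property
    def floor_value(self) -> float:
        """Log-energy value of perfect silence."""
        return float(np.log(self.log_floor))

    def hop(self, rate: int) -> int:
        return int(round(rate / self.frame_rate))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MelSpectrogram:
    """Log-Mel energy image: ``values`` is (n_frames, n_bands)."""

    values: np.ndarray
    frame_rate: float
    band_edges: np.ndarray  # n_bands + 2 strictly increasing Hz edges
    hop: int
    rate: int
    origin_time: float = 0.0
    config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("Mel spectrogram values must be 2-D (frames x bands)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Mel spectrogram contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def band_bounds_hz(self, band: int) -> tuple[float, float]:
        """(lower, upper) edge frequencies of triangular band ``band``."""
        return float(self.band_edges[band]), float(self.band_edges[band + 2])


@dataclass
class FrameLabels:
    """Per-frame binary USV indicator aligned with a Mel spectrogram."""

    values: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("Frame labels must be binary")


def mel_filterbank(config: FeatureConfig, rate: int) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Mel filterbank.

    Returns ``(weights, band_edges)`` with ``weights`` of shape
    (n_bands, n_fft // 2 + 1) and ``band_edges`` the n_bands + 2 Hz band-edge
    frequencies (band i spans edges[i] .. edges[i+2], peak at edges[i+1]).
    """
    if rate < 2 * config.fmax_hz:
        raise ValueError(
            f"Sampling rate {rate} Hz cannot resolve the {config.fmax_hz:g} Hz "
            "upper band edge (Nyquist too low)"
        )
    mel_edges = np.linspace(
        hz_to_mel(config.fmin_hz), hz_to_mel(config.fmax_hz), config.n_bands + 2
    )
    band_edges = mel_to_hz(mel_edges)
    fft_freqs = np.fft.rfftfreq(config.n_fft, d=1.0 / rate)
    lower = band_edges[:-2, None]
    peak = band_edges[1:-1, None]
    upper = band_edges[2:, None]
    up = (fft_freqs[None, :] - lower) / (peak - lower)
    down = (upper - fft_freqs[None, :]) / (upper - peak)
    weights = np.clip(np.minimum(up, down), 0.0, None)
    return weights, band_edges


def melspec(waveform: Waveform, config: FeatureConfig | None = None) -> MelSpectrogram:
    """Log-Mel spectrogram of a waveform.

    Frame t is the Hann-windowed power spectrum of samples
    [t*hop, t*hop + win_length), pooled through the triangular Mel filterbank,
    floored at ``log_floor`` and natural-log compressed.  The tail of the
    signal is zero-padded so the final frame is full-width.
    """
    config = config or FeatureConfig()
    weights, band_edges = mel_filterbank(config, waveform.rate)
    x = waveform.samples
    if x.size < config.win_length:
        raise ValueError(
            f"Waveform of {x.size} samples is shorter than one analysis "
            f"window ({config.win_length})"
        )
    hop = config.hop(waveform.rate)
    n_frames = x.size // hop
    pad = max(0, (n_frames - 1) * hop + config.win_length - x.size)
    if pad:
        x = np.concatenate([x, np.zeros(pad)])
    idx = np.arange(config.win_length)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(config.win_length)[None, :]
    spectrum = np.fft.rfft(frames, n=config.n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    energies = power @ weights.T
    values = np.log(energies + config.log_floor)
    return MelSpectrogram(
        values=values,
        frame_rate=waveform.rate / hop,
        band_edges=band_edges,
        hop=hop,
        rate=waveform.rate,
        origin_time=0.5 * hop / waveform.rate,
        config=config,
    )


def context_windows(spec: MelSpectrogram, k: int = 25) -> np.ndarray:
    """All (n_bands x 2k+1) context patches, one per frame.

    Returns an array of shape (n_frames, n_bands, 2k+1); edge frames are
    padded with the silence floor value so every patch is full-width.  Column
    k of window t equals frame t of the spectrogram.
    """
    if k < 1:
        raise ValueError(f"Context half-width k must be >= 1, got {k}")
    if spec.n_frames == 0:
        raise ValueError("Cannot window an empty spectrogram")
    padded = np.pad(
        spec.values,
        ((k, k), (0, 0)),
        mode="constant",
        constant_values=spec.config.floor_value,
    )
    # sliding view along time gives (n_frames, n_bands, 2k+1) directly
    view = np.lib.stride_tricks.sliding_window_view(padded, 2 * k + 1, axis=0)
    return np.ascontiguousarray(view)


def labels_to_frames(
    table: LabelTable, frame_rate: float, n_frames: int
) -> FrameLabels:
    """Binary frame labels: frame t is 1 iff its span intersects a USV row.

    Frame t owns the half-open span [t, t+1)/frame_rate.  AC and noise rows
    are ignored; overlapping USV rows are merged first.
    """
    values = np.zeros(n_frames, dtype=np.int8)
    t = np.arange(n_frames)
    starts = t / frame_rate
    ends = (t + 1) / frame_rate
    for onset, offset in merge_usv_rows(table):
        values[(starts < offset) & (ends > onset)] = 1
    return FrameLabels(values=values, frame_rate=frame_rate)
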