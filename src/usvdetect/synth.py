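"""Synthetic USV recordings with ground truth, and recording-budget arithmetic.

The generator emulates the statistical structure the detector assumes:
frequency-modulated sweep syllables confined to 30–110 kHz, 10–150 ms long,
grouped into calls with short inter-syllable gaps, over a background of
Gaussian noise, continuous humming tones (horizontal spectrogram lines) and
Poisson-timed broadband impulses (vertical lines).  Syllable amplitude is
calibrated iteratively against the evaluation module's own local-SNR
definition so a requested SNR is realized in the written audio.

It is a statistical stand-in, not an acoustic model of real mouse calls: no
harmonics, no reverberation, no microphone response.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .audio_io import LabelTable, Waveform
from .evaluate import local_snr

__all__ = [
    "SynthConfig",
    "RecordingSchedule",
    "SyllableSpec",
    "synth_syllable",
    "synth_recording",
    "synth_corpus",
    "schedule_hours",
    "usv_fraction",
    "noise_pool_minutes",
]

SWEEP_SHAPES = ("up", "down", "arc", "jump")


@dataclass
class SyllableSpec:
    """One frequency-modulated syllable: shape, band, duration, amplitude."""

    duration: float              # s
    f_start: float               # Hz
    f_end: float                 # Hz
    shape: str = "up"            # one of SWEEP_SHAPES
    amplitude: float = 0.1       # peak a.u.
    ramp_fraction: float = 0.15  # raised-cosine onset/offset fraction

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"Syllable duration must be positive, got {self.duration}")
        if self.shape not in SWEEP_SHAPES:
            raise ValueError(f"Unknown sweep shape {self.shape!r}")
        if min(self.f_start, self.f_end) <= 0:
            raise ValueError("Syllable frequencies must be positive")


@dataclass
class SynthConfig:
    """Recording-level generation parameters.

    Defaults produce a one-second clip with one call of 2–4 syllables — the
    condensed, USV-dense regime the detector is trained on (roughly a quarter
    of the frames contain vocal energy, the rest background).
    """

    rate: int = 250_000
    duration: float = 1.0
    n_calls: int = 1
    syllables_per_call: tuple[int, int] = (2, 4)     # uniform inclusive
    syllable_duration: tuple[float, float] = (0.01, 0.15)
    sweep_range_hz: tuple[float, float] = (30_000.0, 110_000.0)
    max_sweep_extent_hz: float = 40_000.0
    gap_range: tuple[float, float] = (0.03, 0.10)    # within-call gaps, s
    call_gap_range: tuple[float, float] = (0.2, 0.5)
    amplitude: float = 0.1
    noise_floor: float = 0.01                        # Gaussian sigma, a.u.
    humming_freqs_hz: tuple[float, ...] = (5_000.0, 20_000.0, 45_000.0)
    humming_level: float = 0.005
    impulse_rate: float = 2.0                        # events/s (Poisson)
    impulse_level: float = 0.15
    impulse_duration: float = 0.001                  # s
    target_local_snr: float | None = 2.0
    snr_calibration_iters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sweep_range_hz
        if not 0 < lo < hi < self.rate / 2:
            raise ValueError(
                f"Sweep range {self.sweep_range_hz} must lie inside (0, Nyquist)"
            )
        if self.duration <= 0:
            raise ValueError("Recording duration must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RecordingSchedule:
    """Recording-budget factors; total minutes is the product of all factors.

    The adult paradigm uses strains x social groups x pairs x days x
    hours-per-night x minutes-per-hour; the pup paradigm uses strains x
    pups x minutes-per-pup (pass ``groups=days=hours=1``).
    """

    strains: int = 1
    groups: int = 1
    pairs: int = 1
    days: int = 1
    hours: int = 1
    minutes: int = 1

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if int(v) <= 0:
                raise ValueError(f"Schedule field {name} must be positive, got {v}")


def schedule_hours(schedule: RecordingSchedule) -> float:
    """Total recorded hours: product of schedule factors in minutes / 60."""
    minutes = (
        schedule.strains
        * schedule.groups
        * schedule.pairs
        * schedule.days
        * schedule.hours
        * schedule.minutes
    )
    return minutes / 60.0


def usv_fraction(usv_minutes: float, total_hours: float) -> float:
    """Percent of recorded time containing USVs, to two decimals."""
    if total_hours <= 0:
        raise ValueError("total_hours must be positive")
    return round(100.0 * usv_minutes / (60.0 * total_hours), 2)


def noise_pool_minutes(n_files: int, clip_len_s: float = 1.0) -> float:
    """Minutes of background audio in a pool of fixed-length noise clips."""
    return n_files * clip_len_s / 60.0


def synth_syllable(
    spec: SyllableSpec, rate: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Generate one FM syllable; returns (samples, (f_low, f_high)).

    The instantaneous frequency follows the requested sweep shape between
    ``f_start`` and ``f_end`` ("arc" bows halfway beyond the band midpoint,
    "jump" switches frequency at the midpoint); the envelope is raised-cosine
    at both ends.  The returned bounds are the true extent of the
    instantaneous-frequency trace.
    """
    n = int(round(spec.duration * rate))
    if n < 2:
        raise ValueError("Syllable too short for the sampling rate")
    t01 = np.linspace(0.0, 1.0, n)
    f0, f1 = spec.f_start, spec.f_end
    if spec.shape == "up":
        if f1 < f0:
            f0, f1 = f1, f0
        f_inst = f0 + (f1 - f0) * t01
    elif spec.shape == "down":
        if f1 > f0:
            f0, f1 = f1, f0
        f_inst = f0 + (f1 - f0) * t01
    elif spec.shape == "arc":
        mid = 0.5 * (f0 + f1)
        bow = 0.35 * abs(f1 - f0) + 2_000.0
        f_inst = mid + (f0 - mid) * np.cos(np.pi * t01) + bow * np.sin(np.pi * t01)
    else:  # jump
        f_inst = np.where(t01 < 0.5, f0, f1)
    nyquist = rate / 2
    if f_inst.max() >= nyquist:
        raise ValueError(
            f"Syllable reaches {f_inst.max():.0f} Hz, at or above Nyquist {nyquist:.0f} Hz"
        )
    phase = 2 * np.pi * np.cumsum(f_inst) / rate
    ramp_n = max(1, int(spec.ramp_fraction * n))
    envelope = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    envelope[:ramp_n] = ramp
    envelope[-ramp_n:] = ramp[::-1]
    samples = spec.amplitude * envelope * np.sin(phase)
    return samples, (float(f_inst.min()), float(f_inst.max()))


def _draw_syllables(
    config: SynthConfig, rng: np.random.Generator
) -> list[list[SyllableSpec]]:
    """Syllable specs grouped by call."""
    lo_f, hi_f = config.sweep_range_hz
    calls = []
    for _ in range(config.n_calls):
        n_syll = int(rng.integers(config.syllables_per_call[0],
                                  config.syllables_per_call[1] + 1))
        call = []
        for _ in range(n_syll):
            dur = float(rng.uniform(*config.syllable_duration))
            shape = SWEEP_SHAPES[int(rng.integers(len(SWEEP_SHAPES)))]
            f_a = float(rng.uniform(lo_f, hi_f))
            extent = float(rng.uniform(5_000.0, config.max_sweep_extent_hz))
            f_b = float(np.clip(f_a + rng.choice([-1, 1]) * extent, lo_f, hi_f))
            call.append(SyllableSpec(
                duration=dur, f_start=f_a, f_end=f_b, shape=shape,
                amplitude=config.amplitude,
            ))
        calls.append(call)
    return calls


def _place_syllables(
    config: SynthConfig, calls: list[list[SyllableSpec]], rng: np.random.Generator
) -> list[float]:
    """Non-overlapping onset times: within-call gaps, larger between calls."""
    margin = 0.02
    onsets: list[float] = []
    t = margin
    for ci, call in enumerate(calls):
        if ci > 0:
            t += float(rng.uniform(*config.call_gap_range))
        for si, spec in enumerate(call):
            if si > 0:
                t += float(rng.uniform(*config.gap_range))
            onsets.append(t)
            t += spec.duration
    span = t + margin
    if span > config.duration:
        raise ValueError(
            f"Requested syllables span {span:.3f} s but the recording is "
            f"{config.duration:.3f} s"
        )
    # random global offset so calls are not glued to the clip start
    slack = config.duration - span
    shift = float(rng.uniform(0.0, slack)) if slack > 0 else 0.0
    return [o + shift for o in onsets]


def _render(
    config: SynthConfig,
    specs: list[SyllableSpec],
    onsets: list[float],
    rng_noise: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    n = int(round(config.duration * config.rate))
    x = rng_noise.normal(0.0, config.noise_floor, size=n)
    t = np.arange(n) / config.rate
    for f in config.humming_freqs_hz:
        phase0 = rng_noise.uniform(0, 2 * np.pi)
        x += config.humming_level * np.sin(2 * np.pi * f * t + phase0)
    n_impulses = rng_noise.poisson(config.impulse_rate * config.duration)
    imp_len = max(1, int(config.impulse_duration * config.rate))
    for _ in range(n_impulses):
        start = int(rng_noise.integers(0, max(1, n - imp_len)))
        x[start : start + imp_len] += rng_noise.normal(
            0.0, config.impulse_level, size=imp_len
        )
    rows = []
    for spec, onset in zip(specs, onsets):
        chunk, _ = synth_syllable(spec, config.rate)
        i0 = int(round(onset * config.rate))
        x[i0 : i0 + chunk.size] += chunk
        rows.append((i0 / config.rate, (i0 + chunk.size) / config.rate))
    return x, rows


def synth_recording(config: SynthConfig | None = None) -> tuple[Waveform, LabelTable]:
    """Generate one recording and its ground-truth annotation table.

    Syllables never overlap; the truth rows are exactly the placed syllable
    spans.  When ``target_local_snr`` is set, syllable amplitudes are rescaled
    over a few iterations until the median measured local SNR is within a few
    percent of the target (measured with :func:`usvdetect.evaluate.local_snr`,
    so generator and evaluator agree by construction).
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    calls = _draw_syllables(config, rng)
    specs = [s for call in calls for s in call]
    onsets = _place_syllables(config, calls, rng) if specs else []
    noise_seed = int(rng.integers(0, 2**31))

    def render() -> tuple[Waveform, LabelTable]:
        x, rows = _render(config, specs, onsets, np.random.default_rng(noise_seed))
        table = LabelTable(
            rows=pd.DataFrame(
                {
                    "onset": [r[0] for r in rows],
                    "offset": [r[1] for r in rows],
                    "label": ["USV"] * len(rows),
                }
            ),
            source="synthetic",
        )
        return Waveform(samples=x, rate=config.rate), table

    wave, table = render()
    if specs and config.target_local_snr is not None:
        for _ in range(config.snr_calibration_iters):
            report = local_snr(wave, table)
            measured = report.median
            if not np.isfinite(measured) or measured <= 0:
                factor = 2.0
            else:
                if abs(measured - config.target_local_snr) / config.target_local_snr < 0.02:
                    break
                # R ~ A^2 / (2 sigma^2): scale amplitude by sqrt of the ratio
                factor = float(np.sqrt(config.target_local_snr / measured))
            for spec in specs:
                spec.amplitude *= factor
            wave, table = render()
    return wave, table


def synth_corpus(
    n_recordings: int,
    config: SynthConfig | None = None,
    seed: int = 0,
    noise_only: bool = False,
) -> list[tuple[Waveform, LabelTable]]:
    """A list of independent recordings sharing one base configuration.

    Each recording gets its own seed derived from ``seed``.  With
    ``noise_only`` the calls are suppressed (background-only clips, empty
    truth tables) — the noise-pool side of the training mix.
    """
    base = config or SynthConfig()
    out = []
    root = np.random.default_rng(seed)
    for _ in range(n_recordings):
        cfg_dict = base.to_dict()
        cfg_dict["seed"] = int(root.integers(0, 2**31))
        if noise_only:
            cfg_dict["n_calls"] = 0
        out.append(synth_recording(SynthConfig(**cfg_dict)))
    return out
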