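"""Training-time augmentation of log-Mel feature maps.

Three augmentations give the classifier its robustness: shifting the map
along the frequency axis (new vocal ranges), jittering the value scale and
offset (acquisition-gain tolerance, since short segments cannot be globally
normalized), and injecting horizontal/vertical lines that mimic continuous
humming and broadband impulse noise.  Gaussian and salt-and-pepper noise are
implemented but disabled by default — they were not found helpful.

Maps here are (n_bands, n_frames) arrays of log-Mel energies.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "AugmentConfig",
    "shift_frequency",
    "jitter_values",
    "inject_lines",
    "gaussian_noise",
    "salt_pepper_noise",
    "augment_map",
]

N_BANDS = 124

#: Value-scale a.u. -> multiplicative gain on log energies: gain = exp(s / SCALE_AU_DIV).
SCALE_AU_DIV = 6.0


@dataclass
class AugmentConfig:
    """Augmentation ranges and per-augmentation application probabilities.

    ``value_offset_range`` is an additive re-centering of the log energies in
    arbitrary units (a.u.); ``value_scale_range`` is a gain in the same a.u.,
    mapped to a multiplicative factor ``exp(s / 6)`` so the neutral value 0
    is the identity.  ``freq_shift_range`` is in Mel bands.
    """

    freq_shift_range: tuple[int, int] = (-15, 15)
    value_offset_range: tuple[float, float] = (-50.0, 10.0)
    value_scale_range: tuple[float, float] = (-3.0, 3.0)
    line_count_range: tuple[int, int] = (1, 4)
    line_intensity_range: tuple[float, float] = (1.0, 8.0)
    p_shift: float = 0.5
    p_jitter: float = 0.5
    p_lines: float = 0.5
    p_gaussian: float = 0.0
    p_salt_pepper: float = 0.0
    gaussian_sigma: float = 0.5
    salt_pepper_fraction: float = 0.01
    floor_value: float = float(np.log(1e-10))

    def __post_init__(self) -> None:
        for name in (
            "freq_shift_range",
            "value_offset_range",
            "value_scale_range",
            "line_count_range",
            "line_intensity_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be an ordered pair, got ({lo}, {hi})")
        for name in ("p_shift", "p_jitter", "p_lines", "p_gaussian", "p_salt_pepper"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    def to_dict(self) -> dict:
        return asdict(self)


def shift_frequency(
    feature_map: np.ndarray, shift_bands: int, fill_value: float | None = None
) -> np.ndarray:
    """Shift a map along the frequency (band) axis.

    Band b of the input appears at band ``b + shift_bands`` of the output;
    bands shifted past either edge are dropped and vacated bands are filled
    with the silence floor.  Shape is preserved.
    """
    feature_map = np.asarray(feature_map, dtype=np.float64)
    n_bands = feature_map.shape[0]
    if abs(shift_bands) >= n_bands:
        raise ValueError(
            f"|shift| must be < {n_bands} bands, got {shift_bands}"
        )
    if fill_value is None:
        fill_value = float(np.log(1e-10))
    out = np.full_like(feature_map, fill_value)
    if shift_bands >= 0:
        out[shift_bands:, :] = feature_map[: n_bands - shift_bands, :]
    else:
        out[: n_bands + shift_bands, :] = feature_map[-shift_bands:, :]
    return out


def jitter_values(feature_map: np.ndarray, offset: float, scale: float) -> np.ndarray:
    """Affine value jitter: ``out = map * exp(scale / 6) + offset``.

    ``scale`` and ``offset`` are in the log-energy a.u. of the map; scale 0
    and offset 0 is the identity.
    """
    factor = float(np.exp(scale / SCALE_AU_DIV))
    return np.asarray(feature_map, dtype=np.float64) * factor + offset


def scale_factor(scale: float) -> float:
    """The multiplicative gain applied by :func:`jitter_values` for ``scale`` a.u."""
    return float(np.exp(scale / SCALE_AU_DIV))


def inject_lines(
    feature_map: np.ndarray,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add random full-width horizontal (humming) and full-height vertical
    (impulse) lines.

    Returns ``(augmented_map, rows, cols)`` where ``rows``/``cols`` are the
    indices that received a line.  Values only increase, and only on those
    rows/columns.  Counts are uniform over ``line_count_range`` per
    orientation and intensities uniform over ``line_intensity_range``.
    """
    config = config or AugmentConfig()
    out = np.asarray(feature_map, dtype=np.float64).copy()
    n_rows, n_cols = out.shape
    lo, hi = config.line_count_range
    n_h = int(rng.integers(lo, hi + 1))
    n_v = int(rng.integers(lo, hi + 1))
    rows = rng.choice(n_rows, size=min(n_h, n_rows), replace=False)
    cols = rng.choice(n_cols, size=min(n_v, n_cols), replace=False)
    a, b = config.line_intensity_range
    for r in rows:
        out[r, :] += rng.uniform(a, b)
    for c in cols:
        out[:, c] += rng.uniform(a, b)
    return out, np.sort(rows), np.sort(cols)


def gaussian_noise(
    feature_map: np.ndarray, rng: np.random.Generator, sigma: float
) -> np.ndarray:
    """Additive white Gaussian noise on the log energies (off by default)."""
    out = np.asarray(feature_map, dtype=np.float64)
    return out + rng.normal(0.0, sigma, size=out.shape)


def salt_pepper_noise(
    feature_map: np.ndarray,
    rng: np.random.Generator,
    fraction: float,
    low: float,
    high: float,
) -> np.ndarray:
    """Set a random fraction of cells to ``low`` or ``high`` (off by default)."""
    out = np.asarray(feature_map, dtype=np.float64).copy()
    mask = rng.random(out.shape) < fraction
    salt = rng.random(out.shape) < 0.5
    out[mask & salt] = high
    out[mask & ~salt] = low
    return out


def augment_map(
    feature_map: np.ndarray,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Apply the configured augmentation pipeline to one map.

    Each augmentation fires independently with its configured probability.
    Returns the augmented map and a log dict of what was applied.  With all
    probabilities 0 this is the identity.
    """
    config = config or AugmentConfig()
    out = np.asarray(feature_map, dtype=np.float64)
    log: dict = {"shift": None, "jitter": None, "lines": None,
                 "gaussian": False, "salt_pepper": False}
    if rng.random() < config.p_shift:
        lo, hi = config.freq_shift_range
        shift = int(rng.integers(lo, hi + 1))
        out = shift_frequency(out, shift, fill_value=config.floor_value)
        log["shift"] = shift
    if rng.random() < config.p_jitter:
        offset = float(rng.uniform(*config.value_offset_range))
        scale = float(rng.uniform(*config.value_scale_range))
        out = jitter_values(out, offset, scale)
        log["jitter"] = (offset, scale)
    if rng.random() < config.p_lines:
        out, rows, cols = inject_lines(out, rng, config)
        log["lines"] = (rows.tolist(), cols.tolist())
    if rng.random() < config.p_gaussian:
        out = gaussian_noise(out, rng, config.gaussian_sigma)
        log["gaussian"] = True
    if rng.random() < config.p_salt_pepper:
        out = salt_pepper_noise(
            out, rng, config.salt_pepper_fraction,
            low=config.floor_value, high=float(out.max()),
        )
        log["salt_pepper"] = True
    return out, log
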