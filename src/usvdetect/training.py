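"""Dataset engineering and the training loop.

Vocal activity is sparse in long recordings, so the training data is first
*condensed*: USVs separated by less than a second are chained, and each chain
becomes a short (1–20 s) clip.  Background-only noise clips are then mixed in
to teach the model what silence and interference look like; the resulting
frame-class imbalance is handled by weighting the softmax cross-entropy with
the inverse class prevalence (a 25% USV / 75% background mix yields weights
0.75 / 0.25).

Training runs on one-second (332-frame) segments with map-level augmentation,
an Adam optimizer, and an 80/20 train/validation split made at the clip level
so overlapping frames never leak across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .audio_io import LabelTable, Waveform
from .augment import AugmentConfig, augment_map
from .features import FeatureConfig, labels_to_frames, melspec
from .model import (
    HybridUsvModel,
    ModelConfig,
    load_checkpoint,
    save_checkpoint,
    softmax_loss_and_grad,
)

__all__ = [
    "TrainConfig",
    "TrainingSet",
    "condense_segments",
    "assemble_dataset",
    "train_model",
]


@dataclass
class TrainConfig:
    segment_len_range: tuple[float, float] = (1.0, 20.0)  # s
    max_gap: float = 1.0                                  # s, chain-breaking gap
    noise_clip_len: float = 1.0                           # s
    clip_pad: float = 0.1                                 # s of context each side
    epochs: int = 6
    batch_size: int = 32
    learning_rate: float = 1e-3
    segment_frames: int = 332
    val_fraction: float = 0.2
    grad_clip: float = 5.0
    seed: int = 0
    init_checkpoint: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.segment_len_range
        if not 0 < lo <= hi:
            raise ValueError(f"segment_len_range must be ordered and positive, got ({lo}, {hi})")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


def condense_segments(
    table: LabelTable,
    config: TrainConfig | None = None,
    total_duration: float | None = None,
) -> list[tuple[float, float]]:
    """Condense a label table into USV-dense clip intervals.

    USVs whose inter-USV gap is below ``max_gap`` are chained; each chain is
    emitted as one clip (padded by ``clip_pad`` of context on each side,
    clamped so clips never overlap).  Chains longer than the upper segment
    length are split recursively at their largest internal gap.  Every USV
    row ends up inside exactly one clip.
    """
    config = config or TrainConfig()
    spans = table.usv_intervals()
    if len(spans) == 0:
        return []
    # chain by gap
    chains: list[list[tuple[float, float]]] = [[tuple(spans[0])]]
    for onset, offset in spans[1:]:
        if onset - chains[-1][-1][1] < config.max_gap:
            chains[-1].append((onset, offset))
        else:
            chains.append([(onset, offset)])

    min_len, max_len = config.segment_len_range
    max_span = max_len - 2 * config.clip_pad  # leave room for the pads

    def split(chain: list[tuple[float, float]]) -> list[list[tuple[float, float]]]:
        if chain[-1][1] - chain[0][0] <= max_span or len(chain) == 1:
            return [chain]
        gaps = [chain[i + 1][0] - chain[i][1] for i in range(len(chain) - 1)]
        cut = int(np.argmax(gaps))
        return split(chain[: cut + 1]) + split(chain[cut + 1 :])

    pieces = [p for chain in chains for p in split(chain)]
    clips = [
        [p[0][0] - config.clip_pad, p[-1][1] + config.clip_pad] for p in pieces
    ]
    # stretch short clips toward the minimum segment length
    for c in clips:
        short = min_len - (c[1] - c[0])
        if short > 0:
            c[0] -= short / 2
            c[1] += short / 2
    # clamp so clips never overlap each other or the recording bounds;
    # the midpoint of the inter-chain gap keeps every USV inside its clip
    for i in range(1, len(clips)):
        if clips[i][0] < clips[i - 1][1]:
            mid = 0.5 * (pieces[i - 1][-1][1] + pieces[i][0][0])
            clips[i - 1][1] = min(clips[i - 1][1], mid)
            clips[i][0] = max(clips[i][0], mid)
    clips[0][0] = max(clips[0][0], 0.0)
    if total_duration is not None:
        clips[-1][1] = min(clips[-1][1], total_duration)
    return [(a, b) for a, b in clips]


@dataclass
class TrainingSet:
    """Framed training examples: maps are (n, bands, segment_frames)."""

    maps: np.ndarray
    labels: np.ndarray            # (n, segment_frames) binary
    clip_ids: np.ndarray          # (n,) provenance for leakage-free splits
    prevalence: float             # fraction of USV frames
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    @property
    def class_weights(self) -> tuple[float, float]:
        """(USV, background) inverse-prevalence weights, summing to 1."""
        p = min(max(self.prevalence, 1e-6), 1 - 1e-6)
        return (1.0 - p, p)

    def __len__(self) -> int:
        return self.maps.shape[0]


def _segment_clip(
    wave: Waveform, table: LabelTable, fcfg: FeatureConfig, n_seg_frames: int
):
    """Cut one clip into fixed-length (map, labels) training segments."""
    spec = melspec(wave, fcfg)
    labels = labels_to_frames(table, spec.frame_rate, spec.n_frames).values
    feature_map = spec.values.T  # (bands, frames)
    floor = fcfg.floor_value
    segments = []
    for s in range(0, spec.n_frames, n_seg_frames):
        m = feature_map[:, s : s + n_seg_frames]
        y = labels[s : s + n_seg_frames]
        if m.shape[1] < n_seg_frames:
            if m.shape[1] < n_seg_frames // 4:
                continue  # ignore tiny tail remnants
            pad = n_seg_frames - m.shape[1]
            m = np.pad(m, ((0, 0), (0, pad)), constant_values=floor)
            y = np.pad(y, (0, pad))
        segments.append((m, y))
    return segments


def assemble_dataset(
    clips,
    noise_clips,
    features_config: FeatureConfig | None = None,
    segment_frames: int = 332,
) -> TrainingSet:
    """Build the framed training set from USV clips plus noise clips.

    ``clips`` and ``noise_clips`` are sequences of (Waveform, LabelTable)
    pairs; a noise clip whose table contains USV rows is rejected.  Returns
    the segments together with the measured USV frame prevalence that drives
    the class weighting.
    """
    fcfg = features_config or FeatureConfig()
    maps, labels, clip_ids = [], [], []
    cid = 0
    for wave, table in clips:
        for m, y in _segment_clip(wave, table, fcfg, segment_frames):
            maps.append(m)
            labels.append(y)
            clip_ids.append(cid)
        cid += 1
    for wave, table in noise_clips:
        if len(table.usv_intervals()):
            raise ValueError(
                f"Noise clip {table.source!r} contains labeled USVs"
            )
        for m, y in _segment_clip(wave, table, fcfg, segment_frames):
            maps.append(m)
            labels.append(y)
            clip_ids.append(cid)
        cid += 1
    if not maps:
        raise ValueError("No training segments were produced")
    maps_arr = np.stack(maps)
    labels_arr = np.stack(labels).astype(np.int8)
    return TrainingSet(
        maps=maps_arr,
        labels=labels_arr,
        clip_ids=np.asarray(clip_ids),
        prevalence=float(labels_arr.mean()),
        feature_config=fcfg,
    )


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            g = g.astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )


def _frame_f1(track: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    pred = track >= threshold
    truth = labels == 1
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def train_model(
    dataset: TrainingSet,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    augment_config: AugmentConfig | None = None,
    checkpoint_path=None,
):
    """Train (or fine-tune) the hybrid model on a framed dataset.

    Returns ``(model, history)`` where ``history`` is one dict per epoch with
    train loss and validation loss/F1.  The best-validation-F1 weights are
    restored at the end (and written to ``checkpoint_path`` if given).  With
    a fixed seed the run is reproducible.
    """
    tcfg = train_config or TrainConfig()
    mcfg = model_config or ModelConfig()
    if mcfg.class_weights == (0.5, 0.5):
        w = dataset.class_weights
        mcfg = ModelConfig(**{**mcfg.to_dict(), "class_weights": w})
    if tcfg.init_checkpoint:
        model = load_checkpoint(tcfg.init_checkpoint)
        if (model.config.bands, model.config.context,
                model.config.cnn_1d, model.config.cnn_2d,
                model.config.lstm_hidden, model.config.fc_hidden) != (
                mcfg.bands, mcfg.context, mcfg.cnn_1d, mcfg.cnn_2d,
                mcfg.lstm_hidden, mcfg.fc_hidden):
            raise ValueError(
                "Architecture in init_checkpoint does not match model_config"
            )
        model.config.class_weights = mcfg.class_weights
    else:
        model = HybridUsvModel(mcfg)
    rng = np.random.default_rng(tcfg.seed)

    # clip-level 80/20 split (no frame leakage between train and validation)
    clip_ids = np.unique(dataset.clip_ids)
    perm = rng.permutation(clip_ids)
    n_val = max(1, int(round(tcfg.val_fraction * len(perm)))) if len(perm) > 1 else 0
    val_clips = set(perm[:n_val].tolist())
    val_idx = np.flatnonzero(np.isin(dataset.clip_ids, list(val_clips)))
    train_idx = np.flatnonzero(~np.isin(dataset.clip_ids, list(val_clips)))
    if train_idx.size == 0:
        train_idx, val_idx = val_idx, train_idx

    optimizer = _Adam(model.params, tcfg.learning_rate)
    k = model.config.context
    floor = model.floor_value
    weights = model.config.class_weights
    history = []
    best = {"f1": -1.0, "params": {n: p.copy() for n, p in model.params.items()}}

    def run_validation():
        if val_idx.size == 0:
            return float("nan"), float("nan")
        losses, tracks, labs = [], [], []
        for s in range(0, val_idx.size, tcfg.batch_size):
            idx = val_idx[s : s + tcfg.batch_size]
            x = dataset.maps[idx].astype(model.dtype)
            y = dataset.labels[idx]
            xp = np.pad(x, ((0, 0), (0, 0), (k, k)), constant_values=floor)
            mask, _ = model.cnn_forward(xp)
            logits, _ = model.lstm_forward(mask.transpose(0, 2, 1))
            loss, _ = softmax_loss_and_grad(logits, y, weights)
            losses.append(loss * idx.size)
            p = np.exp(logits[..., 1] - np.logaddexp(logits[..., 0], logits[..., 1]))
            tracks.append(p.ravel())
            labs.append(y.ravel())
        val_loss = float(np.sum(losses) / val_idx.size)
        f1 = _frame_f1(np.concatenate(tracks), np.concatenate(labs))
        return val_loss, f1

    for epoch in range(tcfg.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_aug = 0
        for s in range(0, order.size, tcfg.batch_size):
            idx = order[s : s + tcfg.batch_size]
            x = dataset.maps[idx].astype(np.float64)
            y = dataset.labels[idx]
            if augment_config is not None:
                x = x.copy()
                for bi in range(x.shape[0]):
                    x[bi], log = augment_map(x[bi], rng, augment_config)
                    n_aug += sum(v not in (None, False) for v in log.values())
            x = x.astype(model.dtype)
            xp = np.pad(x, ((0, 0), (0, 0), (k, k)), constant_values=floor)
            mask, cnn_cache = model.cnn_forward(xp, want_cache=True)
            logits, seq_cache = model.lstm_forward(
                mask.transpose(0, 2, 1), want_cache=True
            )
            loss, dlogits = softmax_loss_and_grad(logits, y, weights)
            epoch_loss += loss * idx.size
            dmask_seq, seq_grads = model.lstm_backward(
                dlogits.astype(model.dtype), seq_cache
            )
            _, cnn_grads = model.cnn_backward(
                dmask_seq.transpose(0, 2, 1), cnn_cache
            )
            grads = {**seq_grads, **cnn_grads}
            if tcfg.grad_clip:
                norm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                   for g in grads.values()))
                if norm > tcfg.grad_clip:
                    scale = tcfg.grad_clip / norm
                    grads = {n: g * scale for n, g in grads.items()}
            optimizer.step(model.params, grads)
        val_loss, val_f1 = run_validation()
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(order.size, 1),
                "val_loss": val_loss,
                "val_f1": val_f1,
                "n_augmentations": n_aug,
            }
        )
        if not np.isnan(val_f1) and val_f1 >= best["f1"]:
            best = {"f1": val_f1, "params": {n: p.copy() for n, p in model.params.items()}}

    if best["f1"] >= 0:
        model.params = best["params"]
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return model, history
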