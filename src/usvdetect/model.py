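"""The hybrid CNN–BiLSTM ultrasonic-vocalization detector.

Two stages share one 124-band log-Mel input image:

* **CNN frequency-masking stage.**  Every frame is seen as a 124 x 51 patch
  (the frame plus 25 context frames per side).  A 1-D convolution branch over
  the patch's mid column accentuates candidate USV frequencies; a 2-D
  convolution branch over the whole patch (time-valid, then mean-pooled over
  time) suppresses structured noise.  The branch outputs are multiplied and
  squashed with a sigmoid into a per-frame, per-band frequency mask in [0,1].
  Multiplying the input patch by its mask column yields the filtered patch
  used later for denoising.

* **BiLSTM frame classifier.**  The mask columns form a sequence that a
  single bidirectional LSTM layer reads in both directions; a fully connected
  layer and a two-class softmax turn each frame into P(USV)/P(background).
  Training minimizes a class-weighted softmax cross-entropy, with weights set
  to the inverse class prevalence of the training frames.

Everything — convolutions, the LSTM, and their gradients — is implemented
directly on NumPy arrays; convolutions run as im2col matrix products so the
heavy lifting stays inside BLAS.  The CNN stage is exactly frame-local: a
frame's mask column depends only on its own 51-frame context, because the
time axis is never zero-padded inside the convolution stack (the map is
padded once, with the silence floor, at its outer edges).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numba
import numpy as np

from .features import FeatureConfig, MelSpectrogram

__all__ = [
    "ModelConfig",
    "FrequencyMask",
    "ProbabilityTrack",
    "HybridUsvModel",
    "weighted_cross_entropy",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Configuration and output containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters (all layer sizes are config-exposed).

    ``cnn_1d`` / ``cnn_2d`` are lists of (kernel, channels); the 1-D branch
    convolves along frequency only, the 2-D branch uses square kernels,
    'same' along frequency and 'valid' along time.  ``class_weights`` is the
    (USV, background) pair, normalized to sum to 1.
    """

    context: int = 25
    bands: int = 124
    cnn_1d: tuple = ((7, 16), (7, 1))
    cnn_2d: tuple = ((5, 8), (5, 16), (5, 1))
    lstm_hidden: int = 64
    fc_hidden: tuple = ()
    class_weights: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.context < 1:
            raise ValueError(f"context must be >= 1, got {self.context}")
        w_usv, w_bg = self.class_weights
        if w_usv <= 0 or w_bg <= 0:
            raise ValueError("class weights must be positive")
        total = w_usv + w_bg
        self.class_weights = (w_usv / total, w_bg / total)
        if self.cnn_1d[-1][1] != 1 or self.cnn_2d[-1][1] != 1:
            raise ValueError("final conv layer of each branch must have 1 channel")
        shrink = sum(k - 1 for k, _ in self.cnn_2d)
        if shrink >= 2 * self.context + 1:
            raise ValueError("2-D conv stack consumes more time steps than the context window")

    @property
    def window_width(self) -> int:
        return 2 * self.context + 1

    @property
    def pool_width(self) -> int:
        """Time extent left for mean pooling after the valid 2-D convs."""
        return self.window_width - sum(k - 1 for k, _ in self.cnn_2d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FrequencyMask:
    """(n_bands, n_frames) per-frequency USV probabilities in [0, 1]."""

    values: np.ndarray
    frame_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("Frequency mask values must lie in [0, 1]")


@dataclass
class ProbabilityTrack:
    """Per-frame P(USV) in [0, 1]; P(background) is the complement."""

    values: np.ndarray
    frame_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("Track values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Primitive layers (forward + backward)
# ---------------------------------------------------------------------------

def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@numba.njit(fastmath=True, cache=False)
def _conv_fwd_kernel(xp, w, b, out):  # pragma: no cover - exercised via _conv_forward
    B, C_in, Fp, T_in = xp.shape
    C_out, _, kf, kt = w.shape
    F = Fp - kf + 1
    T_out = T_in - kt + 1
    for bi in range(B):
        for co in range(C_out):
            for f in range(F):
                for t in range(T_out):
                    out[bi, co, f, t] = b[co]
            for ci in range(C_in):
                for i in range(kf):
                    for j in range(kt):
                        wv = w[co, ci, i, j]
                        for f in range(F):
                            for t in range(T_out):
                                out[bi, co, f, t] += wv * xp[bi, ci, f + i, t + j]


@numba.njit(fastmath=True, cache=False)
def _conv_bwd_dw_kernel(xp, dout, dw):  # pragma: no cover
    B, C_in, Fp, T_in = xp.shape
    C_out, _, kf, kt = dw.shape
    F = Fp - kf + 1
    T_out = T_in - kt + 1
    for bi in range(B):
        for co in range(C_out):
            for ci in range(C_in):
                for i in range(kf):
                    for j in range(kt):
                        acc = dw[co, ci, i, j]
                        for f in range(F):
                            for t in range(T_out):
                                acc += dout[bi, co, f, t] * xp[bi, ci, f + i, t + j]
                        dw[co, ci, i, j] = acc


@numba.njit(fastmath=True, cache=False)
def _conv_bwd_dx_kernel(w, dout, dxp):  # pragma: no cover
    B, C_in, Fp, T_in = dxp.shape
    C_out, _, kf, kt = w.shape
    F = Fp - kf + 1
    T_out = T_in - kt + 1
    for bi in range(B):
        for ci in range(C_in):
            for co in range(C_out):
                for i in range(kf):
                    for j in range(kt):
                        wv = w[co, ci, i, j]
                        for f in range(F):
                            for t in range(T_out):
                                dxp[bi, ci, f + i, t + j] += wv * dout[bi, co, f, t]


def _conv_forward(x, w, b):
    """'Same'-in-frequency, 'valid'-in-time 2-D convolution.

    x: (B, C_in, F, T_in); w: (C_out, C_in, kf, kt); b: (C_out,).
    Returns (B, C_out, F, T_out) with T_out = T_in - kt + 1.
    """
    B, C_in, F, T_in = x.shape
    C_out, _, kf, kt = w.shape
    T_out = T_in - kt + 1
    pf = kf // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pf, kf - 1 - pf), (0, 0)))
    out = np.empty((B, C_out, F, T_out), dtype=x.dtype)
    _conv_fwd_kernel(xp, w, b.astype(x.dtype), out)
    return out


def _conv_backward(x, w, dout, need_dx: bool = True):
    """Gradients of :func:`_conv_forward` w.r.t. x, w, b."""
    B, C_in, F, T_in = x.shape
    C_out, _, kf, kt = w.shape
    pf = kf // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pf, kf - 1 - pf), (0, 0)))
    dw = np.zeros_like(w)
    dout = np.ascontiguousarray(dout)
    _conv_bwd_dw_kernel(xp, dout, dw)
    db = dout.sum(axis=(0, 2, 3))
    dx = None
    if need_dx:
        dxp = np.zeros_like(xp)
        _conv_bwd_dx_kernel(w, dout, dxp)
        dx = dxp[:, :, pf : pf + F, :]
    return dx, dw, db


def _mean_pool_forward(x, width: int):
    """Sliding mean over the last (time) axis, stride 1.

    x: (B, F, T_in) -> (B, F, T_in - width + 1).
    """
    c = np.cumsum(x, axis=-1, dtype=np.float64)
    c = np.concatenate([np.zeros_like(c[..., :1]), c], axis=-1)
    return ((c[..., width:] - c[..., :-width]) / width).astype(x.dtype)


def _mean_pool_backward(dout, width: int, T_in: int):
    """Scatter the sliding-mean gradient back to the input length."""
    g = dout / width
    c = np.cumsum(g, axis=-1, dtype=np.float64)
    c = np.concatenate([np.zeros_like(c[..., :1]), c], axis=-1)
    T_out = dout.shape[-1]
    u = np.arange(T_in)
    hi = np.minimum(u, T_out - 1)
    lo = np.maximum(u - width + 1, 0)
    # din[u] = sum_{t=lo..hi} g[t]; empty where lo > hi (cannot happen here)
    din = c[..., hi + 1] - c[..., lo]
    return din.astype(dout.dtype)


class _Lstm:
    """One-directional LSTM layer with manual backpropagation through time."""

    def __init__(self, params: dict, prefix: str):
        self.params = params
        self.prefix = prefix

    def forward(self, x):
        """x: (B, T, F_in) -> h: (B, T, H), plus caches for backward."""
        p = self.params
        wx, wh, b = p[self.prefix + "wx"], p[self.prefix + "wh"], p[self.prefix + "b"]
        B, T, _ = x.shape
        H = wh.shape[0]
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        hs = np.empty((B, T, H), dtype=x.dtype)
        caches = []
        xw = x @ wx  # precompute all input projections at once
        for t in range(T):
            z = xw[:, t, :] + h @ wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        return hs, (x, caches)

    def backward(self, dh_seq, cache):
        x, caches = cache
        p = self.params
        wx, wh = p[self.prefix + "wx"], p[self.prefix + "wh"]
        B, T, F_in = x.shape
        H = wh.shape[0]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros_like(p[self.prefix + "b"])
        dx = np.empty_like(x)
        dh = np.zeros((B, H), dtype=x.dtype)
        dc = np.zeros((B, H), dtype=x.dtype)
        dz_seq = np.empty((B, T, 4 * H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = caches[t]
            dh_t = dh + dh_seq[:, t, :]
            do = dh_t * tc
            dct = dh_t * o * (1 - tc * tc) + dc
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dc = dct * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dz_seq[:, t, :] = dz
            dwh += h_prev.T @ dz
            dh = dz @ wh.T
        flat_dz = dz_seq.reshape(B * T, 4 * H)
        dwx += x.reshape(B * T, F_in).T @ flat_dz
        db += flat_dz.sum(axis=0)
        dx[:] = (flat_dz @ wx.T).reshape(B, T, F_in)
        return dx, {self.prefix + "wx": dwx, self.prefix + "wh": dwh, self.prefix + "b": db}


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class HybridUsvModel:
    """Parameter container plus forward/backward passes for both stages."""

    def __init__(self, config: ModelConfig | None = None, dtype=np.float32):
        self.config = config or ModelConfig()
        self.dtype = dtype
        self.floor_value = FeatureConfig().floor_value
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # -- initialization ----------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(self.dtype)

        c_in = 1
        for li, (k, c_out) in enumerate(cfg.cnn_1d):
            self.params[f"c1.{li}.w"] = he((c_out, c_in, k, 1), c_in * k)
            self.params[f"c1.{li}.b"] = np.zeros(c_out, dtype=self.dtype)
            c_in = c_out
        c_in = 1
        for li, (k, c_out) in enumerate(cfg.cnn_2d):
            self.params[f"c2.{li}.w"] = he((c_out, c_in, k, k), c_in * k * k)
            self.params[f"c2.{li}.b"] = np.zeros(c_out, dtype=self.dtype)
            c_in = c_out
        H = cfg.lstm_hidden
        bound = 1.0 / np.sqrt(H)
        for prefix in ("lstm_fw.", "lstm_bw."):
            self.params[prefix + "wx"] = rng.uniform(
                -bound, bound, (cfg.bands, 4 * H)
            ).astype(self.dtype)
            self.params[prefix + "wh"] = rng.uniform(-bound, bound, (H, 4 * H)).astype(
                self.dtype
            )
            b = np.zeros(4 * H, dtype=self.dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
            self.params[prefix + "b"] = b
        widths = (2 * H, *cfg.fc_hidden, 2)
        for li, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
            bound = 1.0 / np.sqrt(w_in)
            self.params[f"fc.{li}.w"] = rng.uniform(-bound, bound, (w_in, w_out)).astype(
                self.dtype
            )
            self.params[f"fc.{li}.b"] = np.zeros(w_out, dtype=self.dtype)
        self.n_fc = len(widths) - 1

    # -- CNN stage ---------------------------------------------------------

    def cnn_forward(self, padded_maps, want_cache: bool = False):
        """Mask columns for an already context-padded map stack.

        padded_maps: (B, F, T + 2*context) -> mask (B, F, T).
        """
        cfg = self.config
        x = np.asarray(padded_maps, dtype=self.dtype)
        B, F, Tp = x.shape
        k = cfg.context
        T = Tp - 2 * k
        if F != cfg.bands or T < 1:
            raise ValueError(
                f"Padded map of shape {x.shape} incompatible with "
                f"{cfg.bands} bands and context {k}"
            )
        cache: dict = {"x": x}
        # 1-D branch on per-frame columns (time kernel 1, so no shrink)
        a = x[:, None, :, :]
        acts1 = []
        for li in range(len(cfg.cnn_1d)):
            a = _conv_forward(a, self.params[f"c1.{li}.w"], self.params[f"c1.{li}.b"])
            if li < len(cfg.cnn_1d) - 1:
                acts1.append(a)
                a = np.maximum(a, 0)
        b1_full = a[:, 0, :, :]               # (B, F, Tp)
        b1 = b1_full[:, :, k : k + T]         # mid columns of each window
        # 2-D branch, time-valid
        a = x[:, None, :, :]
        acts2 = []
        for li in range(len(cfg.cnn_2d)):
            a = _conv_forward(a, self.params[f"c2.{li}.w"], self.params[f"c2.{li}.b"])
            if li < len(cfg.cnn_2d) - 1:
                acts2.append(a)
                a = np.maximum(a, 0)
        conv2_out = a[:, 0, :, :]             # (B, F, Tp - shrink)
        b2 = _mean_pool_forward(conv2_out, cfg.pool_width)  # (B, F, T)
        prod = b1 * b2
        mask = _sigmoid(prod)
        if want_cache:
            cache.update(
                acts1=acts1, acts2=acts2, b1=b1, b2=b2,
                conv2_T=conv2_out.shape[-1], mask=mask, T=T,
            )
            return mask, cache
        return mask, None

    def cnn_backward(self, dmask, cache):
        cfg = self.config
        x = cache["x"]
        B, F, Tp = x.shape
        k, T = cfg.context, cache["T"]
        mask = cache["mask"]
        dprod = dmask * mask * (1 - mask)
        db1 = dprod * cache["b2"]
        db2 = dprod * cache["b1"]
        grads: dict[str, np.ndarray] = {}
        # 2-D branch
        dconv2 = _mean_pool_backward(db2, cfg.pool_width, cache["conv2_T"])
        da = dconv2[:, None, :, :]
        inputs2 = [x[:, None, :, :]] + [np.maximum(a, 0) for a in cache["acts2"]]
        for li in range(len(cfg.cnn_2d) - 1, -1, -1):
            din, dw, db = _conv_backward(
                inputs2[li], self.params[f"c2.{li}.w"], da, need_dx=li > 0
            )
            grads[f"c2.{li}.w"] = dw
            grads[f"c2.{li}.b"] = db
            if li > 0:
                da = din * (cache["acts2"][li - 1] > 0)
        # 1-D branch: scatter mid-column grads back to full width
        db1_full = np.zeros((B, 1, F, Tp), dtype=x.dtype)
        db1_full[:, 0, :, k : k + T] = db1
        da = db1_full
        inputs1 = [x[:, None, :, :]] + [np.maximum(a, 0) for a in cache["acts1"]]
        for li in range(len(cfg.cnn_1d) - 1, -1, -1):
            din, dw, db = _conv_backward(
                inputs1[li], self.params[f"c1.{li}.w"], da, need_dx=li > 0
            )
            grads[f"c1.{li}.w"] = dw
            grads[f"c1.{li}.b"] = db
            if li > 0:
                da = din * (cache["acts1"][li - 1] > 0)
        return None, grads

    # -- sequence stage ----------------------------------------------------

    def lstm_forward(self, mask_seq, want_cache: bool = False):
        """mask_seq: (B, T, F) mask columns -> logits (B, T, 2)."""
        x = np.asarray(mask_seq, dtype=self.dtype)
        fw = _Lstm(self.params, "lstm_fw.")
        bw = _Lstm(self.params, "lstm_bw.")
        h_fw, cache_fw = fw.forward(x)
        h_bw_rev, cache_bw = bw.forward(x[:, ::-1, :])
        h = np.concatenate([h_fw, h_bw_rev[:, ::-1, :]], axis=2)
        a = h
        fc_inputs = []
        for li in range(self.n_fc):
            fc_inputs.append(a)
            a = a @ self.params[f"fc.{li}.w"] + self.params[f"fc.{li}.b"]
            if li < self.n_fc - 1:
                a = np.maximum(a, 0)
        logits = a
        if want_cache:
            return logits, {"cache_fw": cache_fw, "cache_bw": cache_bw,
                            "fc_inputs": fc_inputs}
        return logits, None

    def lstm_backward(self, dlogits, cache):
        grads: dict[str, np.ndarray] = {}
        da = dlogits
        for li in range(self.n_fc - 1, -1, -1):
            a_in = cache["fc_inputs"][li]
            B, T, w_in = a_in.shape
            flat_in = a_in.reshape(B * T, w_in)
            flat_da = da.reshape(B * T, -1)
            grads[f"fc.{li}.w"] = flat_in.T @ flat_da
            grads[f"fc.{li}.b"] = flat_da.sum(axis=0)
            da = (flat_da @ self.params[f"fc.{li}.w"].T).reshape(B, T, w_in)
            if li > 0:
                da = da * (a_in > 0)
        H = self.config.lstm_hidden
        dh = da
        fw = _Lstm(self.params, "lstm_fw.")
        bw = _Lstm(self.params, "lstm_bw.")
        dx_fw, g_fw = fw.backward(dh[:, :, :H], cache["cache_fw"])
        dx_bw_rev, g_bw = bw.backward(dh[:, ::-1, H:], cache["cache_bw"])
        grads.update(g_fw)
        grads.update(g_bw)
        return dx_fw + dx_bw_rev[:, ::-1, :], grads

    # -- spec-level operations --------------------------------------------

    def cnn_mask(self, window):
        """Mask column and filtered patch for one 124 x 51 context window."""
        cfg = self.config
        window = np.asarray(window, dtype=np.float64)
        if window.shape != (cfg.bands, cfg.window_width):
            raise ValueError(
                f"Expected window of shape ({cfg.bands}, {cfg.window_width}), "
                f"got {window.shape}"
            )
        mask, _ = self.cnn_forward(window[None, :, :])
        column = mask[0, :, 0].astype(np.float64)
        filtered = window * column[:, None]
        return column, filtered

    def classify_sequence(self, mask_columns, frame_rate: float = float("nan")) -> ProbabilityTrack:
        """P(USV) track for a (n_frames, n_bands) sequence of mask columns."""
        x = np.asarray(mask_columns, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError("classify_sequence needs a nonempty (frames x bands) array")
        logits, _ = self.lstm_forward(x[None, :, :])
        p = _softmax(logits.astype(np.float64))
        return ProbabilityTrack(values=p[0, :, 1], frame_rate=frame_rate)

    def pad_map(self, feature_map):
        """Context-pad a (F, T) map with the silence floor on the time axis."""
        k = self.config.context
        return np.pad(
            np.asarray(feature_map, dtype=self.dtype),
            ((0, 0), (k, k)),
            constant_values=self.dtype(self.floor_value),
        )


def _softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(track, labels, class_weights) -> float:
    """Class-weighted cross-entropy of a P(USV) track against binary labels.

    ``loss = -mean_t w(label_t) * log P(label_t)`` with ``class_weights``
    given as the (USV, background) pair.  Zero only in the limit of perfect
    confidence.
    """
    track = np.asarray(track, dtype=np.float64)
    labels = np.asarray(labels)
    if track.shape != labels.shape:
        raise ValueError(
            f"track ({track.shape}) and labels ({labels.shape}) must align"
        )
    w_usv, w_bg = class_weights
    if w_usv <= 0 or w_bg <= 0:
        raise ValueError("class weights must be positive")
    p_label = np.where(labels == 1, track, 1.0 - track)
    w = np.where(labels == 1, w_usv, w_bg)
    with np.errstate(divide="ignore"):
        ll = np.log(p_label)
    return float(-(w * ll).mean())


def softmax_loss_and_grad(logits, labels, class_weights):
    """Weighted softmax cross-entropy and its gradient w.r.t. the logits.

    logits: (..., 2) with channel 1 = USV; labels broadcastable {0,1}.
    The loss is the weighted mean of per-frame -log p(label).
    """
    p = _softmax(logits.astype(np.float64))
    labels = np.asarray(labels)
    n = labels.size
    w_usv, w_bg = class_weights
    w = np.where(labels == 1, w_usv, w_bg)
    p_label = np.where(labels == 1, p[..., 1], p[..., 0])
    loss = float(-(w * np.log(np.maximum(p_label, 1e-30))).mean())
    onehot = np.stack([(labels == 0), (labels == 1)], axis=-1).astype(np.float64)
    dlogits = (w[..., None] * (p - onehot)) / n
    return loss, dlogits


def predict(
    spec: MelSpectrogram | np.ndarray,
    model: HybridUsvModel,
    segment_len: int = 332,
    frame_rate: float | None = None,
) -> tuple[ProbabilityTrack, FrequencyMask]:
    """Run both stages over a full spectrogram.

    The CNN stage is frame-local, so it runs over the whole (context-padded)
    map in one pass; the BiLSTM reads the mask in ``segment_len``-frame
    segments (the training regime) and the tracks are concatenated.
    """
    if isinstance(spec, MelSpectrogram):
        feature_map = spec.values.T  # (bands, frames)
        fr = spec.frame_rate
    else:
        feature_map = np.asarray(spec)
        fr = float("nan") if frame_rate is None else frame_rate
    if frame_rate is not None:
        fr = frame_rate
    n_frames = feature_map.shape[1]
    padded = model.pad_map(feature_map)
    mask, _ = model.cnn_forward(padded[None, :, :])
    mask = mask[0].astype(np.float64)  # (bands, frames)
    track = np.empty(n_frames, dtype=np.float64)
    for s in range(0, n_frames, segment_len):
        seg = mask[:, s : s + segment_len].T[None, :, :]
        logits, _ = model.lstm_forward(seg)
        track[s : s + segment_len] = _softmax(logits.astype(np.float64))[0, :, 1]
    return (
        ProbabilityTrack(values=track, frame_rate=fr),
        FrequencyMask(values=mask, frame_rate=fr),
    )


def save_checkpoint(model: HybridUsvModel, path) -> None:
    """Single-file checkpoint: weights plus the embedded architecture config."""
    meta = json.dumps(model.config.to_dict())
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **model.params)


def load_checkpoint(path, dtype=np.float32) -> HybridUsvModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        for key in ("cnn_1d", "cnn_2d", "class_weights", "fc_hidden"):
            if key in meta and meta[key] is not None:
                meta[key] = tuple(tuple(v) if isinstance(v, list) else v for v in meta[key])
        config = ModelConfig(**meta)
        model = HybridUsvModel(config, dtype=dtype)
        for name in model.params:
            model.params[name] = data[name].astype(dtype)
    return model
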