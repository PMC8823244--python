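"""Scoring detections against manual truth, and signal-to-noise ratios.

Matching taxonomy
-----------------
Detections are matched to truth USVs chronologically.  The first detection to
overlap a truth is a true positive (category ``USV``); later detections that
only re-tag already-found truths are ``Partial``; a single detection spanning
two or more truths is ``Multi`` and counts as one true positive (the extra
truths it covers are consumed, not double-counted).  Unmatched detections are
false positives, uncovered truths are misses.  Alarm-call (``AC``) truth rows
are excluded before matching.

SNR
---
The magnitude of an audio segment is the mean of its squared samples.  The
local SNR of USV i is ``R_i = (M_sig+bg,i - M_bg,i) / M_bg,i`` where
``M_sig+bg,i`` is the magnitude of the segment containing the USV and
``M_bg,i`` the mean magnitude of the flanking non-USV segments.  R is zero
when the signal span is no louder than its surroundings.  The global SNR
pools all USV samples against all non-USV samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import LabelTable, Waveform, merge_usv_rows

__all__ = [
    "DetectionMatch",
    "MetricsReport",
    "SnrReport",
    "magnitude",
    "local_snr",
    "global_snr",
    "match_detections",
    "metrics",
    "snr_stratified_metrics",
]

MATCH_CATEGORIES = ("USV", "Partial", "Multi", "FalsePositive", "Missed")


@dataclass
class DetectionMatch:
    """One matching outcome: a detection (or an unmatched truth)."""

    category: str
    detection: tuple[float, float] | None
    truths: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in MATCH_CATEGORIES:
            raise ValueError(f"Unknown match category {self.category!r}")


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float
    recall_defined: bool = True
    precision_defined: bool = True


@dataclass
class SnrReport:
    """Per-USV local SNR rows; NaN where the background magnitude is zero."""

    r: np.ndarray              # R_i per USV
    m_sig_bg: np.ndarray       # magnitude of each USV-containing segment
    m_bg: np.ndarray           # mean flanking background magnitude
    undefined: np.ndarray      # boolean flags (background magnitude zero/empty)

    @property
    def median(self) -> float:
        valid = self.r[~self.undefined]
        return float(np.median(valid)) if valid.size else float("nan")


def magnitude(segment: np.ndarray) -> float:
    """Mean of squared samples of a raw-audio segment."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size == 0:
        raise ValueError("Cannot compute the magnitude of an empty segment")
    return float(np.mean(segment**2))


def _slice(waveform: Waveform, t0: float, t1: float) -> np.ndarray:
    i0 = max(0, int(round(t0 * waveform.rate)))
    i1 = min(waveform.samples.size, int(round(t1 * waveform.rate)))
    return waveform.samples[i0:i1]


def local_snr(waveform: Waveform, truth: LabelTable) -> SnrReport:
    """Local SNR R_i for every (merged) USV span in the truth table.

    The background flanks of USV i are the non-USV gaps immediately before
    and after it (bounded by the neighboring USVs or the recording edges);
    M_bg,i is the mean of the two flank magnitudes (or the single available
    one at a recording edge).
    """
    spans = merge_usv_rows(truth)
    n = len(spans)
    r = np.full(n, np.nan)
    m_sig = np.full(n, np.nan)
    m_bg = np.full(n, np.nan)
    undefined = np.ones(n, dtype=bool)
    duration = waveform.duration
    for i, (onset, offset) in enumerate(spans):
        seg = _slice(waveform, onset, offset)
        if seg.size == 0:
            continue
        m_sig[i] = magnitude(seg)
        prev_end = spans[i - 1][1] if i > 0 else 0.0
        next_start = spans[i + 1][0] if i + 1 < n else duration
        flanks = []
        before = _slice(waveform, prev_end, onset)
        after = _slice(waveform, offset, next_start)
        if before.size:
            flanks.append(magnitude(before))
        if after.size:
            flanks.append(magnitude(after))
        if not flanks:
            continue
        m_bg[i] = float(np.mean(flanks))
        if m_bg[i] > 0:
            r[i] = (m_sig[i] - m_bg[i]) / m_bg[i]
            undefined[i] = False
    return SnrReport(r=r, m_sig_bg=m_sig, m_bg=m_bg, undefined=undefined)


def global_snr(waveform: Waveform, truth: LabelTable) -> float:
    """Global SNR: all USV samples pooled against all non-USV samples.

    Returns NaN (flagged undefined) when there are no USVs, no background,
    or silent background.
    """
    spans = merge_usv_rows(truth)
    if len(spans) == 0:
        return float("nan")
    mask = np.zeros(waveform.samples.size, dtype=bool)
    for onset, offset in spans:
        i0 = max(0, int(round(onset * waveform.rate)))
        i1 = min(mask.size, int(round(offset * waveform.rate)))
        mask[i0:i1] = True
    sig = waveform.samples[mask]
    bg = waveform.samples[~mask]
    if sig.size == 0 or bg.size == 0:
        return float("nan")
    m_bg = magnitude(bg)
    if m_bg == 0:
        return float("nan")
    return (magnitude(sig) - m_bg) / m_bg


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return min(a[1], b[1]) - max(a[0], b[0])


def _iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = max(0.0, _overlap(a, b))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def match_detections(
    detections,
    truth: LabelTable,
    min_iou: float = 0.0,
) -> list[DetectionMatch]:
    """Greedy chronological matching of detections to truth USVs.

    ``detections`` is an iterable of objects with ``onset``/``offset``
    attributes or (onset, offset) pairs.  A detection overlaps a truth when
    their temporal intersection is positive and the IoU is at least
    ``min_iou`` (default 0: any overlap counts).
    """
    det_spans = []
    for d in detections:
        if hasattr(d, "onset"):
            det_spans.append((float(d.onset), float(d.offset)))
        else:
            det_spans.append((float(d[0]), float(d[1])))
    det_spans.sort()
    truths = [tuple(row) for row in merge_usv_rows(truth)]
    covered = [False] * len(truths)
    matches: list[DetectionMatch] = []
    for span in det_spans:
        hits = [
            j
            for j, t in enumerate(truths)
            if _overlap(span, t) > 0 and _iou(span, t) >= min_iou
        ]
        if not hits:
            matches.append(DetectionMatch("FalsePositive", span))
            continue
        new = [j for j in hits if not covered[j]]
        for j in hits:
            covered[j] = True
        if len(hits) >= 2 and new:
            matches.append(DetectionMatch("Multi", span, [truths[j] for j in hits]))
        elif new:
            matches.append(DetectionMatch("USV", span, [truths[j] for j in hits]))
        else:
            matches.append(DetectionMatch("Partial", span, [truths[j] for j in hits]))
    for j, t in enumerate(truths):
        if not covered[j]:
            matches.append(DetectionMatch("Missed", None, [t]))
    return matches


def metrics(matches: list[DetectionMatch], partial_as_fp: bool = False) -> MetricsReport:
    """Recall, precision and F1 from a match list.

    tp counts ``USV`` and ``Multi`` matches (each once); fp counts
    ``FalsePositive`` (plus ``Partial`` when ``partial_as_fp``); fn counts
    ``Missed`` truths.  Undefined ratios are reported as 0 and flagged.
    """
    tp = sum(1 for m in matches if m.category in ("USV", "Multi"))
    fp = sum(1 for m in matches if m.category == "FalsePositive")
    if partial_as_fp:
        fp += sum(1 for m in matches if m.category == "Partial")
    fn = sum(1 for m in matches if m.category == "Missed")
    recall_defined = (tp + fn) > 0
    precision_defined = (tp + fp) > 0
    recall = tp / (tp + fn) if recall_defined else 0.0
    precision = tp / (tp + fp) if precision_defined else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MetricsReport(
        tp=tp, fp=fp, fn=fn,
        recall=recall, precision=precision, f1=f1,
        recall_defined=recall_defined, precision_defined=precision_defined,
    )


def snr_stratified_metrics(
    waveform: Waveform,
    truth: LabelTable,
    detections,
    bin_edges=(0.0, 0.1, 0.5, 1.0, 2.0, np.inf),
    min_iou: float = 0.0,
):
    """Recall per local-SNR bin: how detection quality degrades with SNR.

    Truth USVs are binned by their local SNR R_i; within each bin, recall is
    the fraction of that bin's USVs covered by any detection.  (Precision is
    not defined per bin because a false positive has no truth SNR; the
    unstratified precision comes from :func:`metrics`.)  Returns a DataFrame
    with one row per bin: ``snr_low, snr_high, n_usvs, detected, recall``.
    """
    import pandas as pd

    spans = merge_usv_rows(truth)
    report = local_snr(waveform, truth)
    matches = match_detections(detections, truth, min_iou=min_iou)
    missed = {tuple(m.truths[0]) for m in matches if m.category == "Missed"}
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        in_bin = [
            i for i in range(len(spans))
            if not report.undefined[i] and lo <= report.r[i] < hi
        ]
        n = len(in_bin)
        detected = sum(1 for i in in_bin if tuple(spans[i]) not in missed)
        rows.append(
            {
                "snr_low": lo,
                "snr_high": hi,
                "n_usvs": n,
                "detected": detected,
                "recall": detected / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
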