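"""Scoring segmentations against ground truth with Intersection-over-Minimum.

IoM(S, GT) = |S ∩ GT| / min(|S|, |GT|): an overlap score that saturates at 1
whenever one mask contains the other, which makes it forgiving about a
segmenter that over- or under-grows a cell while still centred on it.

Segments and ground truths are matched one-to-one, greedily by descending
IoM; a matched pair counts as a true positive only when its IoM is strictly
larger than the threshold.  Unmatched segments are false positives and
unmatched ground truths false negatives, from which precision, recall and
F-score follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import LabelImage


@dataclass
class MatchReport:
    """TP/FP/FN counts and derived metrics at one IoM threshold."""

    iom_threshold: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fscore: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)


def iom(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A ∩ B| / min(|A|, |B|) for two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("IoM is undefined for an empty mask")
    inter = int((a & b).sum())
    return inter / min(na, nb)


def precision_recall_fscore(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Eqs for P, R, F with the 0/0 convention that empty ratios are 0."""
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    fscore = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    return precision, recall, fscore


def _as_labels(x) -> np.ndarray:
    if isinstance(x, LabelImage):
        return x.data
    return np.asarray(x)


def pairwise_iom(segments, ground_truths) -> list[tuple[int, int, float]]:
    """IoM for every overlapping (segment id, ground-truth id) pair."""
    seg = _as_labels(segments)
    gt = _as_labels(ground_truths)
    if seg.shape != gt.shape:
        raise ValueError("segmentation and ground truth shapes differ")
    areas_s = np.bincount(seg.ravel())
    areas_g = np.bincount(gt.ravel())
    both = (seg > 0) & (gt > 0)
    if not both.any():
        return []
    n_gt = int(gt.max())
    codes = seg[both].astype(np.int64) * (n_gt + 1) + gt[both].astype(np.int64)
    uniq, counts = np.unique(codes, return_counts=True)
    out = []
    for code, inter in zip(uniq, counts):
        s, g = int(code // (n_gt + 1)), int(code % (n_gt + 1))
        out.append((s, g, int(inter) / min(int(areas_s[s]), int(areas_g[g]))))
    return out


def match_regions(segments, ground_truths, iom_threshold: float) -> MatchReport:
    """Greedy one-to-one matching by descending IoM, strict TP inequality."""
    seg = _as_labels(segments)
    gt = _as_labels(ground_truths)
    if seg.shape != gt.shape:
        raise ValueError("segmentation and ground truth shapes differ")
    seg_ids = np.unique(seg)
    gt_ids = np.unique(gt)
    n_seg = int((seg_ids > 0).sum())
    n_gt = int((gt_ids > 0).sum())

    candidates = [p for p in pairwise_iom(seg, gt) if p[2] > iom_threshold]
    # descending IoM, then ids ascending for a deterministic tie-break
    candidates.sort(key=lambda p: (-p[2], p[0], p[1]))
    used_s: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for s, g, v in candidates:
        if s in used_s or g in used_g:
            continue
        used_s.add(s)
        used_g.add(g)
        pairs.append((s, g, v))

    tp = len(pairs)
    fp = n_seg - tp
    fn = n_gt - tp
    precision, recall, fscore = precision_recall_fscore(tp, fp, fn)
    return MatchReport(iom_threshold, tp, fp, fn, precision, recall, fscore, pairs)


def metric_sweep(segments, ground_truths, thresholds) -> list[MatchReport]:
    """One MatchReport per IoM threshold (F-score non-increasing in level)."""
    if any(not (0 < t <= 1) for t in thresholds):
        raise ValueError("IoM thresholds must lie in (0, 1]")
    return [match_regions(segments, ground_truths, t) for t in thresholds]
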