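"""Event-based scoring: interval IoU, bipartite matching, precision/recall/F.

A predicted event counts as a true positive when it can be matched one-to-
one to a positive (POS) ground-truth event with interval IoU >= 30%, using
a maximum-cardinality bipartite matching (ties broken by maximal total
IoU). Unmatched POS events are false negatives. Predictions that fail to
match a POS event but overlap an ambiguous (UNK) ground-truth event at the
same IoU threshold are discarded — neither rewarded nor penalized; the
rest are false positives. Event-based scoring has no bounded true-negative
count, so TN is not computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .events import Event


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn)


@dataclass
class Metrics:
    precision: float
    recall: float
    f_score: float


def interval_iou(a: Event, b: Event) -> float:
    """IoU of two half-open time intervals; 0 when disjoint."""
    inter = min(a.offset_s, b.offset_s) - max(a.onset_s, b.onset_s)
    if inter <= 0:
        return 0.0
    union = max(a.offset_s, b.offset_s) - min(a.onset_s, b.onset_s)
    return inter / union


def _max_matching(iou: np.ndarray, iou_min: float) -> list[tuple[int, int, float]]:
    """Maximum-cardinality matching on edges with IoU >= iou_min.

    Among maximum-cardinality matchings, the one with maximal summed IoU is
    chosen: each valid edge is weighted IoU + C with C larger than any
    achievable total IoU, so cardinality dominates.
    """
    n, m = iou.shape
    if n == 0 or m == 0:
        return []
    valid = iou >= iou_min
    big = float(n + m + 1)
    weights = np.where(valid, iou + big, 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return [(int(r), int(c), float(iou[r, c]))
            for r, c in zip(rows, cols) if valid[r, c]]


def match_events(gt: list[Event], pred: list[Event],
                 iou_min: float = 0.3) -> MatchResult:
    """Score predictions against POS/UNK ground truth (see module docstring)."""
    if iou_min < 0:
        raise ValueError("iou_min must be >= 0")
    pos_idx = [i for i, e in enumerate(gt) if e.status == "POS"]
    unk = [e for e in gt if e.status == "UNK"]
    pos = [gt[i] for i in pos_idx]
    iou = np.array([[interval_iou(g, p) for p in pred] for g in pos]
                   ).reshape(len(pos), len(pred))
    pairs = [(pos_idx[r], c, v) for r, c, v in _max_matching(iou, iou_min)]
    matched_pred = {c for _, c, _ in pairs}
    tp = len(pairs)
    fn = len(pos) - tp
    fp = 0
    for j, p in enumerate(pred):
        if j in matched_pred:
            continue
        if any(interval_iou(u, p) >= iou_min for u in unk):
            continue  # overlaps an ambiguous event: discarded
        fp += 1
    return MatchResult(tp, fp, fn, pairs)


def precision_recall_fscore(tp: int, fp: int, fn: int) -> Metrics:
    """Eq.-style P/R/F with the 0/0 := 0 convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return Metrics(precision, recall, fscore_from_pr(precision, recall))


def fscore_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def pool_matches(results: list[MatchResult]) -> Metrics:
    """Micro-average: sum TP/FP/FN over files, then compute P/R/F."""
    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    fn = sum(r.fn for r in results)
    return precision_recall_fscore(tp, fp, fn)
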