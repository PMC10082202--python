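"""Detection evaluation: box matching, precision/recall, PR curve + AUC,
bootstrap error bars and the two-proportion z-test.

Bootstrap follows the study protocol: 1000 resamples of the testing units.
At patch level the patches themselves are resampled with replacement; at
WSI level each replicate is a uniformly placed axis-aligned crop covering
90% of the slide area, with predictions and ground truth assigned to the
crop by box center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .cv_detector import Detection
from .wsi_detection import iou as box_iou

__all__ = [
    "MatchResult",
    "PRCurve",
    "match_boxes",
    "precision_recall",
    "pr_curve",
    "bootstrap_metrics",
    "two_proportion_ztest",
    "significance_stars",
]


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int, float], ...]  # (pred_idx, gt_idx, iou)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


@dataclass(frozen=True)
class PRCurve:
    thresholds: np.ndarray  # descending scores
    precision: np.ndarray
    recall: np.ndarray
    auc: float


def _center(box):
    return ((box[0] + box[2]) / 2.0, (box[1] + box[3]) / 2.0)


def _center_in(box_pred, box_gt) -> float:
    cx, cy = _center(box_pred)
    inside = box_gt[0] <= cx < box_gt[2] and box_gt[1] <= cy < box_gt[3]
    return 1.0 if inside else 0.0


def match_boxes(
    preds: Sequence[Detection],
    gts: Sequence[Detection],
    iou_thresh: float = 0.5,
    criterion: str = "iou",
) -> MatchResult:
    """Greedy per-class matching by descending prediction score.

    Each prediction takes the unmatched same-label ground-truth box with
    the highest IoU above the threshold (``criterion="center"`` instead
    requires the prediction center inside the GT box, for dot-derived GT).
    Unmatched predictions are FP, unmatched ground truths FN.
    """
    score_fn = box_iou if criterion == "iou" else _center_in
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    taken = [False] * len(gts)
    pairs = []
    for pi in order:
        p = preds[pi]
        best_j, best_s = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j] or g.label != p.label:
                continue
            s = score_fn(p.box, g.box)
            ok = s >= iou_thresh if criterion == "iou" else s > 0
            if ok and s > best_s:
                best_j, best_s = j, s
        if best_j >= 0:
            taken[best_j] = True
            pairs.append((pi, best_j, best_s))
    tp = len(pairs)
    return MatchResult(tp, len(preds) - tp, len(gts) - tp, tuple(pairs))


def precision_recall(
    preds: Sequence[Detection], gts: Sequence[Detection], iou_thresh: float = 0.5
) -> tuple[float, float]:
    m = match_boxes(preds, gts, iou_thresh)
    return m.precision, m.recall


def pr_curve(
    preds: Sequence[Detection], gts: Sequence[Detection], iou_thresh: float = 0.5
) -> PRCurve:
    """Precision-recall sweep over every unique prediction score.

    Matches are assigned once by the greedy matcher; each unique score then
    acts as an operating threshold.  The AUC is the trapezoid over recall,
    opened at recall 0 with the precision of the top-scoring point and
    closed at the maximum recall with its precision.
    """
    if len(gts) == 0:
        raise ValueError("recall is undefined without ground truth")
    if len(preds) == 0:
        return PRCurve(np.array([]), np.array([]), np.array([]), 0.0)
    m = match_boxes(preds, gts, iou_thresh)
    matched = {pi for pi, _, _ in m.pairs}
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    scores = np.array([preds[i].score for i in order])
    is_tp = np.array([i in matched for i in order])
    cum_tp = np.cumsum(is_tp)
    cum_fp = np.cumsum(~is_tp)
    n_gt = len(gts)
    # threshold at each unique score: include all preds with score >= s
    uniq, last_idx = [], []
    for k in range(len(order)):
        if k == len(order) - 1 or scores[k + 1] != scores[k]:
            uniq.append(scores[k])
            last_idx.append(k)
    idx = np.array(last_idx)
    prec = cum_tp[idx] / (cum_tp[idx] + cum_fp[idx])
    rec = cum_tp[idx] / n_gt
    r_pts = np.concatenate([[0.0], rec])
    p_pts = np.concatenate([[prec[0]], prec])
    auc = float(np.trapezoid(p_pts, r_pts))
    return PRCurve(np.array(uniq), prec, rec, auc)


def _default_metric(units) -> dict[str, float]:
    preds = [d for u in units for d in u[0]]
    gts = [d for u in units for d in u[1]]
    tp = fp = fn = 0
    for u_preds, u_gts in units:
        m = match_boxes(u_preds, u_gts)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    return dict(
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn) if tp + fn else 0.0,
    )


def bootstrap_metrics(
    units: Sequence[tuple[Sequence[Detection], Sequence[Detection]]],
    metric_fn: Callable | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    mode: str = "patch",
    slide_shape: tuple[int, int] | None = None,
    area_fraction: float = 0.9,
) -> dict[str, tuple[float, float]]:
    """Bootstrap mean and standard deviation of detection metrics.

    ``units`` are (predictions, ground truths) pairs.  Patch mode resamples
    the units with replacement; WSI mode treats the single unit as one slide
    of shape ``slide_shape`` and draws, per replicate, a uniformly placed
    axis-aligned crop covering ``area_fraction`` of the slide area
    (linear factor sqrt(area_fraction) per side), keeping boxes by center
    inclusion.  Deterministic per seed.
    """
    if len(units) == 0:
        raise ValueError("need at least one unit")
    metric_fn = metric_fn or _default_metric
    rng = np.random.default_rng(seed)
    reps: list[dict[str, float]] = []
    if mode == "patch":
        n = len(units)
        for _ in range(n_boot):
            pick = rng.integers(0, n, size=n)
            reps.append(metric_fn([units[i] for i in pick]))
    elif mode == "wsi":
        if slide_shape is None:
            raise ValueError("WSI mode needs slide_shape")
        preds = [d for u in units for d in u[0]]
        gts = [d for u in units for d in u[1]]
        h, w = slide_shape
        f = np.sqrt(area_fraction)
        ch, cw = f * h, f * w
        for _ in range(n_boot):
            y0 = rng.uniform(0, h - ch)
            x0 = rng.uniform(0, w - cw)
            win = (x0, y0, x0 + cw, y0 + ch)

            def _inside(d):
                cx, cy = _center(d.box)
                return win[0] <= cx < win[2] and win[1] <= cy < win[3]

            reps.append(metric_fn([([d for d in preds if _inside(d)], [d for d in gts if _inside(d)])]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for key in reps[0]:
        vals = np.array([r[key] for r in reps])
        out[key] = (float(vals.mean()), float(vals.std()))
    return out


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled proportion
    p = (x1+x2)/(n1+n2); p-value = 2 (1 - Phi(|z|)).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n > 0")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion: zero variance")
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def significance_stars(p: float) -> str:
    """Printed significance classes: * <0.05, ** <0.01, *** <0.001,
    **** <0.0001, NS otherwise."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "NS"
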