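"""Whole-slide detection orchestration.

A detector trained and evaluated on 1000 x 1000 px patches misses cells that
straddle patch boundaries.  The WSI scheme re-tiles the mosaic with grids
shifted by half a tile horizontally, vertically and diagonally, runs every
detector on every tile (dropping boxes that touch tile borders — the
completely-visible rule), fuses the per-detector outputs into an ensemble,
pools the coverages, removes repeated detections by overlap ratio, and
thresholds by score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cv_detector import Detection

__all__ = [
    "TilingScheme",
    "DetectorHandle",
    "tile_wsi",
    "merge_ensemble",
    "overlap_ratio",
    "iou",
    "dedup",
    "detect_wsi",
]


def _default_coverages(tile_px: int):
    h = tile_px // 2
    return [(0, 0), (0, h), (h, 0), (h, h)]


@dataclass(frozen=True)
class TilingScheme:
    """1000-px tiling with half-shift coverages (H, V and diagonal)."""

    tile_px: int = 1000
    coverages: tuple[tuple[int, int], ...] | None = None
    include_diagonal: bool = True

    def grid_shifts(self) -> list[tuple[int, int]]:
        if self.coverages is not None:
            shifts = list(self.coverages)
        else:
            shifts = _default_coverages(self.tile_px)
            if not self.include_diagonal:
                shifts = shifts[:3]
        if (0, 0) not in shifts:
            raise ValueError("base coverage (0, 0) must be present")
        if any(abs(dy) >= self.tile_px or abs(dx) >= self.tile_px for dy, dx in shifts):
            raise ValueError("coverage shifts must be smaller than the tile")
        return shifts


@dataclass(frozen=True)
class DetectorHandle:
    """A pluggable tile detector: image tile -> detections in tile frame."""

    detect: Callable[[np.ndarray], list[Detection]]
    name: str = "detector"


def tile_wsi(
    mosaic_shape: tuple[int, int], scheme: TilingScheme = TilingScheme()
) -> list[tuple[int, tuple[int, int, int, int]]]:
    """Windows ``(coverage_id, (y0, y1, x0, x1))`` over the mosaic.

    The base coverage's windows tile the full mosaic (edge windows clamped);
    shifted coverages start at their offset and are clipped to the mosaic.
    """
    h, w = mosaic_shape
    t = scheme.tile_px
    if t > h or t > w:
        raise ValueError(f"tile size {t} exceeds mosaic {mosaic_shape}")
    out = []
    for cid, (sy, sx) in enumerate(scheme.grid_shifts()):
        ys = list(range(sy, h, t))
        xs = list(range(sx, w, t))
        for y0 in ys:
            for x0 in xs:
                y1, x1 = min(y0 + t, h), min(x0 + t, w)
                if y1 - y0 < 2 or x1 - x0 < 2:
                    continue
                out.append((cid, (y0, y1, x0, x1)))
    return out


def _box_area(b) -> float:
    return max(b[2] - b[0], 0.0) * max(b[3] - b[1], 0.0)


def _intersection(a, b) -> float:
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return max(w, 0.0) * max(h, 0.0)


def overlap_ratio(box_a, box_b) -> float:
    """Intersection area over the smaller box's area, in [0, 1]."""
    area_a, area_b = _box_area(box_a), _box_area(box_b)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("degenerate box")
    return _intersection(box_a, box_b) / min(area_a, area_b)


def iou(box_a, box_b) -> float:
    """Intersection over union — the config alternative to overlap_ratio."""
    inter = _intersection(box_a, box_b)
    union = _box_area(box_a) + _box_area(box_b) - inter
    return inter / union if union > 0 else 0.0


def merge_ensemble(
    per_model_detections: Sequence[Sequence[Detection]],
    iou_cluster_thresh: float = 0.5,
    min_votes: int = 1,
) -> list[Detection]:
    """Fuse k detectors' outputs on one tile.

    Boxes of the same label are greedily clustered across models at
    IoU >= ``iou_cluster_thresh``; the fused box is the score-weighted mean
    of member coordinates and the fused score is the member-score sum over
    k (absent votes count as zero), so unanimous confident boxes dominate.
    """
    k = len(per_model_detections)
    if k < 1:
        raise ValueError("need at least one detector")
    pool = [
        (mi, d) for mi, dets in enumerate(per_model_detections) for d in dets
    ]
    pool.sort(key=lambda t: (-t[1].score, t[1].y_min, t[1].x_min))
    clusters: list[list[tuple[int, Detection]]] = []
    for mi, d in pool:
        for cluster in clusters:
            rep = cluster[0][1]
            if rep.label == d.label and iou(rep.box, d.box) >= iou_cluster_thresh:
                cluster.append((mi, d))
                break
        else:
            clusters.append([(mi, d)])
    fused = []
    for cluster in clusters:
        scores = np.array([d.score for _, d in cluster])
        boxes = np.array([d.box for _, d in cluster])
        wts = scores / scores.sum() if scores.sum() > 0 else np.full(len(cluster), 1.0 / len(cluster))
        bx = (boxes * wts[:, None]).sum(axis=0)
        if len({mi for mi, _ in cluster}) < min_votes:
            continue
        fused.append(
            Detection(
                float(bx[0]), float(bx[1]), float(bx[2]), float(bx[3]),
                cluster[0][1].label,
                float(min(1.0, scores.sum() / k)),
                int(np.mean([d.region_area_px for _, d in cluster])),
            )
        )
    return fused


def dedup(
    detections: Sequence[Detection], ratio_thresh: float = 0.5, ratio: str = "overlap"
) -> list[Detection]:
    """Remove repeated detections.

    Boxes are visited by descending score (ties: lower y_min, x_min, then
    insertion order); a box is kept unless its overlap ratio (or IoU, per
    ``ratio``) with an already-kept box of the same label reaches
    ``ratio_thresh``.  Idempotent; never drops the top-scoring member of an
    overlap cluster.
    """
    fn = overlap_ratio if ratio == "overlap" else iou
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].score, detections[i].y_min, detections[i].x_min, i),
    )
    kept: list[Detection] = []
    for i in order:
        d = detections[i]
        if any(k.label == d.label and fn(k.box, d.box) >= ratio_thresh for k in kept):
            continue
        kept.append(d)
    return kept


def _touches_border(d: Detection, win, margin: float) -> bool:
    y0, y1, x0, x1 = win
    return (
        d.x_min <= margin
        or d.y_min <= margin
        or d.x_max >= (x1 - x0) - margin
        or d.y_max >= (y1 - y0) - margin
    )


def detect_wsi(
    mosaic,
    detectors: Sequence[DetectorHandle],
    scheme: TilingScheme = TilingScheme(),
    score_thresh: float = 0.0,
    dedup_thresh: float = 0.5,
    border_margin_px: float = 0.0,
    iou_cluster_thresh: float = 0.5,
    channel_names=None,
) -> list[Detection]:
    """Run the full WSI scheme on a (channels, H, W) mosaic.

    Per coverage tile: each detector runs on the crop, boxes touching the
    tile border are dropped (partial-cell rule) and the rest translated to
    the mosaic frame; detectors are fused per tile; all coverages are
    pooled, deduplicated by overlap ratio and thresholded by score.
    Deterministic given deterministic detectors.
    """
    if len(detectors) < 1:
        raise ValueError("need at least one detector")
    if channel_names is None:
        channel_names = getattr(mosaic, "channel_names", None)
    data = np.asarray(getattr(mosaic, "data", mosaic), float)
    h, w = data.shape[-2:]
    pooled: list[Detection] = []
    for cid, (y0, y1, x0, x1) in tile_wsi((h, w), scheme):
        crop = data[..., y0:y1, x0:x1]
        per_model = []
        for handle in detectors:
            dets = handle.detect(crop)
            for d in dets:
                if not (0 <= d.x_min and 0 <= d.y_min and d.x_max <= x1 - x0 and d.y_max <= y1 - y0):
                    raise ValueError(f"detector {handle.name!r} returned an out-of-tile box {d.box}")
            per_model.append([d for d in dets if not _touches_border(d, (y0, y1, x0, x1), border_margin_px)])
        fused = merge_ensemble(per_model, iou_cluster_thresh=iou_cluster_thresh)
        pooled.extend(d.translated(x0, y0) for d in fused)
    kept = dedup(pooled, dedup_thresh)
    return [d for d in kept if d.score >= score_thresh]
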