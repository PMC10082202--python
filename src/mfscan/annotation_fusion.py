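"""Training-label construction: fuse expert dot annotations with CV regions.

Experts mark cells with single dots; the rule-based detector supplies
segmentation regions.  A dot falling inside a region adopts that region's
bounding box; a dot outside every region gets a square box of the empirical
cell diameter centered on it.  Every dot yields exactly one box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import regionprops

__all__ = [
    "AnnotationDot",
    "fuse_annotations",
    "boundary_filter",
    "read_dots_csv",
    "read_dots_json",
]

#: Empirical cell diameters (µm) used for orphan-dot boxes.
EMPIRICAL_DIAMETER_UM = {"mCTC": 15.0, "CAF": 20.0}


@dataclass(frozen=True)
class AnnotationDot:
    x_px: float
    y_px: float
    label: str
    annotator_id: str = ""


def _orphan_box(x: float, y: float, side_px: int) -> tuple[int, int, int, int]:
    # side is exact: x_min = round(x - s/2), half-open x_max = x_min + s
    x0 = int(round(x - side_px / 2.0))
    y0 = int(round(y - side_px / 2.0))
    return (x0, y0, x0 + side_px, y0 + side_px)


def _clip_box(box, shape):
    h, w = shape
    x0, y0, x1, y1 = box
    return (max(x0, 0), max(y0, 0), min(x1, w), min(y1, h))


def fuse_annotations(
    dots: list[AnnotationDot],
    regions: np.ndarray,
    empirical_diameter_px: dict[str, int],
    image_shape: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Pair dots with regions to produce one labeled box per dot.

    Dots are first sorted canonically (y, then x) so the result does not
    depend on input order.  In a region containing several dots, the first
    dot takes the region's bounding box and the rest fall back to
    empirical-diameter boxes (flagged in the ``from_region`` column), so the
    box count always equals the dot count.
    """
    shape = regions.shape if image_shape is None else image_shape
    h, w = shape
    for d in dots:
        if not (0 <= d.x_px < w and 0 <= d.y_px < h):
            raise ValueError(f"dot ({d.x_px}, {d.y_px}) outside image {shape}")
    ordered = sorted(dots, key=lambda d: (d.y_px, d.x_px))
    bbox_by_label: dict[int, tuple] = {
        r.label: (r.bbox[1], r.bbox[0], r.bbox[3], r.bbox[2]) for r in regionprops(regions)
    }
    region_used: set[int] = set()
    rows = []
    for d in ordered:
        lbl = int(regions[int(d.y_px), int(d.x_px)])
        side = int(empirical_diameter_px.get(d.label, max(empirical_diameter_px.values())))
        if lbl > 0 and lbl not in region_used:
            region_used.add(lbl)
            box, from_region = bbox_by_label[lbl], True
        else:
            box, from_region = _orphan_box(d.x_px, d.y_px, side), False
        x0, y0, x1, y1 = _clip_box(box, shape)
        rows.append(
            dict(x_min=x0, y_min=y0, x_max=x1, y_max=y1, label=d.label, score=1.0,
                 from_region=from_region)
        )
    return pd.DataFrame(rows, columns=["x_min", "y_min", "x_max", "y_max", "label", "score", "from_region"])


def boundary_filter(boxes: pd.DataFrame, image_shape: tuple[int, int], margin_px: int = 0) -> pd.DataFrame:
    """Drop boxes touching the image border within ``margin_px`` — only
    completely visible cells are kept for training/testing."""
    h, w = image_shape
    keep = (
        (boxes["x_min"] > margin_px)
        & (boxes["y_min"] > margin_px)
        & (boxes["x_max"] < w - margin_px)
        & (boxes["y_max"] < h - margin_px)
    )
    return boxes[keep].reset_index(drop=True)


def read_dots_csv(path: str | Path) -> list[AnnotationDot]:
    df = pd.read_csv(path)
    return [
        AnnotationDot(float(r.x), float(r.y), str(r.label), str(getattr(r, "annotator_id", "")))
        for r in df.itertuples(index=False)
    ]


def read_dots_json(path: str | Path) -> list[AnnotationDot]:
    """Point annotations as exported by common slide-annotation tools:
    a list of GeoJSON-like features with Point geometry and a
    ``classification`` / ``label`` property."""
    payload = json.loads(Path(path).read_text())
    features = payload.get("features", payload) if isinstance(payload, dict) else payload
    dots = []
    for feat in features:
        geom = feat.get("geometry", feat)
        if geom.get("type", "Point") != "Point":
            continue
        x, y = geom["coordinates"][:2]
        props = feat.get("properties", {})
        label = props.get("classification", {}).get("name") if isinstance(props.get("classification"), dict) else None
        label = label or props.get("label") or feat.get("label", "")
        dots.append(AnnotationDot(float(x), float(y), str(label), str(props.get("annotator_id", ""))))
    return dots
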