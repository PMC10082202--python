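"""Rule-based (conventional computer vision) mCTC / CAF detector.

Mirrors the pathologist screening protocol: the DAPI, CK and FAP channels
are binarized separately; CK- and FAP-positive events are segmented with a
distance-transform watershed, size-filtered, and then cross-checked across
channels — a CK event is accepted as an mCTC only if its interior is DAPI
positive (which rejects hollow filter pores) and FAP negative; the
symmetric rule yields CAFs.  All thresholds are explicit configuration,
standing in for the observer-tuned values of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "DetectorParams",
    "Detection",
    "binarize_channel",
    "segment_events",
    "size_filter",
    "classify_events",
    "cv_detect",
    "detections_to_frame",
    "frame_to_detections",
]

#: Pixel area of an 8 µm circle at 0.23 µm/px — mCTCs are larger than this.
_MIN_CELL_AREA_PX = int(np.pi * (0.5 * 8.0 / 0.23) ** 2 * 0.4)  # ~950, conservative


@dataclass(frozen=True)
class Detection:
    """Axis-aligned half-open box with class label and confidence."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str
    score: float
    region_area_px: int = 0

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate box")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def translated(self, dx: float, dy: float) -> "Detection":
        return Detection(
            self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy,
            self.label, self.score, self.region_area_px,
        )


@dataclass(frozen=True)
class DetectorParams:
    """Observer-tunable detection parameters (all intensities in [0, 1])."""

    thresholds: dict = dc_field(
        default_factory=lambda: {"DAPI": "otsu", "CK": "otsu", "FAP": "otsu"}
    )
    min_area_px: int = _MIN_CELL_AREA_PX
    max_area_px: int = 40 * _MIN_CELL_AREA_PX
    dapi_mean_min: float = 0.10
    negative_mean_max: float = 0.10
    watershed_min_distance_px: int = int(0.6 * 15.0 / 0.23)  # 0.6 x expected diameter
    score_normalizer: float = 0.8

    def __post_init__(self):
        if not 0 < self.min_area_px < self.max_area_px:
            raise ValueError("need 0 < min_area < max_area")
        for v in (self.dapi_mean_min, self.negative_mean_max):
            if not 0.0 <= v <= 1.0:
                raise ValueError("intensity fractions must be in [0, 1]")


def binarize_channel(image: np.ndarray, threshold_spec) -> np.ndarray:
    """Threshold one channel: ``threshold_spec`` is an absolute value in
    [0, 1] or the string ``"otsu"``.  Otsu on a near-constant image (no
    bimodality to exploit) yields an empty mask."""
    img = np.asarray(image, float)
    if threshold_spec == "otsu":
        if img.max() - img.min() < 0.05:
            return np.zeros(img.shape, bool)
        t = threshold_otsu(img)
    else:
        t = float(threshold_spec)
    return img > t


def segment_events(mask: np.ndarray, min_distance_px: int) -> np.ndarray:
    """Distance-transform watershed splitting touching events.

    Seeds are local distance maxima separated by at least
    ``min_distance_px``; regions are 8-connected.  Returns a label image.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask)
    coords = peak_local_max(
        dist, min_distance=max(int(min_distance_px), 1), labels=mask, exclude_border=False
    )
    if len(coords) == 0:
        markers, _ = ndimage.label(mask, structure=np.ones((3, 3)))
        return markers.astype(np.int32)
    seeds = np.zeros(mask.shape, dtype=np.int32)
    seeds[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    return watershed(-dist, seeds, mask=mask, connectivity=2).astype(np.int32)


def size_filter(labels: np.ndarray, min_area_px: int, max_area_px: int) -> np.ndarray:
    """Drop regions with area outside ``[min_area, max_area]`` (inclusive)."""
    out = np.asarray(labels).copy()
    for r in regionprops(out):
        if not (min_area_px <= r.area <= max_area_px):
            out[out == r.label] = 0
    return out


def _mean_in(img: np.ndarray, region_mask: np.ndarray) -> float:
    return float(img[region_mask].mean()) if region_mask.any() else 0.0


def classify_events(
    regions_ck: np.ndarray,
    regions_fap: np.ndarray,
    dapi_img: np.ndarray,
    ck_img: np.ndarray,
    fap_img: np.ndarray,
    params: DetectorParams,
) -> list[Detection]:
    """Cross-channel marker logic.

    A CK region becomes an mCTC iff its interior DAPI mean is at least
    ``dapi_mean_min`` (hollow pores fail this) and its FAP mean is at most
    ``negative_mean_max``; symmetrically for CAFs on FAP regions.  The score
    is the positive-marker mean divided by ``score_normalizer`` (clipped to
    1) — a heuristic confidence so precision-recall sweeps apply uniformly.
    """
    shapes = {regions_ck.shape, regions_fap.shape, dapi_img.shape, ck_img.shape, fap_img.shape}
    if len(shapes) != 1:
        raise ValueError("all images must share one shape")
    out: list[Detection] = []
    for labels, pos_img, neg_img, label_name in (
        (regions_ck, ck_img, fap_img, "mCTC"),
        (regions_fap, fap_img, ck_img, "CAF"),
    ):
        for r in regionprops(labels):
            region_mask = labels == r.label
            if _mean_in(dapi_img, region_mask) < params.dapi_mean_min:
                continue
            if _mean_in(neg_img, region_mask) > params.negative_mean_max:
                continue
            score = min(1.0, _mean_in(pos_img, region_mask) / params.score_normalizer)
            y0, x0, y1, x1 = r.bbox
            out.append(Detection(float(x0), float(y0), float(x1), float(y1), label_name, score, int(r.area)))
    return out


def cv_detect(image, params: DetectorParams = DetectorParams(), channel_names=None) -> list[Detection]:
    """Full rule-based chain: binarize -> watershed -> size filter ->
    cross-channel classification.  ``image`` is a (channels, H, W) array or
    an object with ``data`` and ``channel_names`` (AifTile / AifMosaic)."""
    if channel_names is None:
        channel_names = getattr(image, "channel_names", None)
    data = getattr(image, "data", image)
    data = np.asarray(data, float)
    if channel_names is None:
        raise ValueError("channel_names required for bare arrays")
    names = list(channel_names)
    for needed in ("DAPI", "CK", "FAP"):
        if needed not in names:
            raise KeyError(f"channel {needed!r} missing from {names}")
    dapi = data[names.index("DAPI")]
    ck = data[names.index("CK")]
    fap = data[names.index("FAP")]

    regions = {}
    for ch, img in (("CK", ck), ("FAP", fap)):
        mask = binarize_channel(img, params.thresholds.get(ch, "otsu"))
        labels = segment_events(mask, params.watershed_min_distance_px)
        regions[ch] = size_filter(labels, params.min_area_px, params.max_area_px)
    return classify_events(regions["CK"], regions["FAP"], dapi, ck, fap, params)


# ---------------------------------------------------------------------------
# Detection CSV interchange
# ---------------------------------------------------------------------------

_COLUMNS = ["tile_id", "x_min", "y_min", "x_max", "y_max", "label", "score", "area_px"]


def detections_to_frame(detections: Sequence[Detection], tile_id=0) -> pd.DataFrame:
    rows = [
        dict(
            tile_id=tile_id, x_min=d.x_min, y_min=d.y_min, x_max=d.x_max, y_max=d.y_max,
            label=d.label, score=d.score, area_px=d.region_area_px,
        )
        for d in detections
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_detections(frame: pd.DataFrame) -> list[Detection]:
    return [
        Detection(
            float(r.x_min), float(r.y_min), float(r.x_max), float(r.y_max),
            str(r.label), float(r.score), int(getattr(r, "area_px", 0) or 0),
        )
        for r in frame.itertuples(index=False)
    ]
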