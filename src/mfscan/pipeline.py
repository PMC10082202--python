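"""End-to-end orchestration: simulate -> autofocus -> fine scan -> AIF ->
shade correction -> registration -> stitch -> rule-based detection ->
evaluation.  This is the whole-chain driver used by the CLI and by the
acceptance study."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import aif_preprocess as pre
from . import autofocus as af
from . import cv_detector as cv
from . import evaluation as ev
from . import scene_sim as sim


@dataclass
class PipelineResult:
    mosaic: pre.AifMosaic
    detections: list[cv.Detection]
    gt_boxes: "object"  # DataFrame
    best_z_um: np.ndarray  # per tile
    metrics: dict


def run_slide_pipeline(
    scene: sim.GroundTruthScene,
    optics: sim.OpticsModel,
    scan_grid: tuple[int, int],
    tile_shape_px: tuple[int, int],
    tile_overlap_px: int,
    plan: af.ScanPlan = af.ScanPlan(),
    params: cv.DetectorParams | None = None,
    stage_jitter_px: float = 0.5,
    tilt_rad: float = 0.0005,
    seed: int = 0,
    patch_size_px: int = 128,
    patch_overlap_px: int = 16,
    flatfield: bool = True,
    iou_thresh: float = 0.3,
    registration_max_residual_px: float = 4.0,
) -> PipelineResult:
    """Run the full chain on one simulated slide and score it against the
    simulator's ground truth.

    Autofocus runs per tile in the DAPI channel on the coarse plan; the fine
    z positions centered on each tile's best focus are rendered for all
    channels, fused to AIF tiles, shading-corrected, registered along the
    row-major chain and stitched.  The rule-based detector then runs on the
    mosaic and precision/recall are computed against ground-truth boxes
    (matched at ``iou_thresh``).
    """
    params = params or cv.DetectorParams()
    rows, cols = scan_grid
    h, w = tile_shape_px
    step_y, step_x = h - tile_overlap_px, w - tile_overlap_px
    renderer = af.make_scene_renderer(scene, optics, tile_shape_px)

    # scan: autofocus then fine stack per tile, at jittered true positions
    rng = np.random.default_rng(seed)
    ct, st = np.cos(tilt_rad), np.sin(tilt_rad)
    aif_tiles: list[pre.AifTile] = []
    best_zs = np.zeros(rows * cols)
    for r in range(rows):
        for c in range(cols):
            ny_px, nx_px = r * step_y, c * step_x
            tx = ct * nx_px - st * ny_px
            ty = st * nx_px + ct * ny_px
            if (r, c) != (0, 0) and stage_jitter_px > 0:
                tx += rng.uniform(-stage_jitter_px, stage_jitter_px)
                ty += rng.uniform(-stage_jitter_px, stage_jitter_px)
            if (r, c) == (0, 0):
                tx, ty = 0.0, 0.0
            true_xy = (tx * optics.pixel_size_um, ty * optics.pixel_size_um)
            best_z, _ = af.autofocus_tile(renderer, true_xy, plan)
            best_zs[r * cols + c] = best_z
            fine_z = af.plan_fine_scan(best_z, plan)
            tile = sim.render_tile(scene, optics, true_xy, tile_shape_px, fine_z)
            aif_tiles.append(pre.fuse_aif(tile, patch_size_px, patch_overlap_px))

    if flatfield and len(aif_tiles) >= 3:
        field = pre.estimate_flatfield(aif_tiles, smoothing_sigma_px=max(8, min(h, w) // 10))
        aif_tiles = [pre.apply_flatfield(t, field) for t in aif_tiles]

    # the stage is subpixel-repeatable, so large apparent shifts are
    # spurious matches in sparse overlap strips
    shifts = pre.register_grid(
        aif_tiles, scan_grid, tile_shape_px, tile_overlap_px,
        max_residual_px=registration_max_residual_px,
    )
    mosaic = pre.stitch(aif_tiles, scan_grid, tile_shape_px, tile_overlap_px, shifts)

    detections = cv.cv_detect(mosaic, params)

    gt = sim.ground_truth_boxes(
        scene, optics.pixel_size_um, origin_um=(0.0, 0.0), image_shape_px=mosaic.data.shape[-2:]
    )
    gt_dets = [
        cv.Detection(r.x_min, r.y_min, r.x_max, r.y_max, r.label, 1.0)
        for r in gt.itertuples(index=False)
    ]
    metrics = {}
    for label in ("mCTC", "CAF"):
        p = [d for d in detections if d.label == label]
        g = [d for d in gt_dets if d.label == label]
        if g:
            m = ev.match_boxes(p, g, iou_thresh)
            metrics[label] = dict(precision=m.precision, recall=m.recall, tp=m.tp, fp=m.fp, fn=m.fn)
    return PipelineResult(mosaic, detections, gt, best_zs, metrics)
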