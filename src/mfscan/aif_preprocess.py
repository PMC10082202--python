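"""All-in-focus fusion, shading correction, registration and stitching.

Each fine z-stack tile is compressed to a single all-in-focus (AIF) image by
splitting it into patches (default 600 x 600 px), selecting per patch and per
channel the z-slice with the highest Tenengrad focus measure, and feathering
overlapping patches together.  Channels select their z independently, which
absorbs residual axial chromatic aberration.  Tiles are then flat-field
corrected, registered pairwise by subpixel phase correlation on their overlap
strips, and stitched into a whole-slide mosaic anchored at the upper-left
tile with distance-transform blending.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .autofocus import tenengrad
from .scene_sim import ZStackTile

__all__ = [
    "AifTile",
    "AifMosaic",
    "PairShift",
    "split_patches",
    "fuse_aif",
    "estimate_flatfield",
    "apply_flatfield",
    "register_pair",
    "register_grid",
    "stitch",
    "write_mosaic",
]

#: Fractional-shift edge reflection pad, px (suppresses Fourier wraparound).
EDGE_TAPER_PX = 8


@dataclass
class AifTile:
    """All-in-focus tile: channels x rows x cols, with the per-patch z choice."""

    data: np.ndarray
    stage_xy_um: tuple[float, float]
    channel_names: tuple[str, ...]
    z_choice_map: np.ndarray | None = None  # (channels, n_patch_y, n_patch_x)

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


@dataclass
class AifMosaic:
    """Stitched whole-slide image with per-tile subpixel offsets."""

    data: np.ndarray  # channels x H x W
    tile_offsets_px: np.ndarray  # (n_tiles, 2) (dy, dx) relative to anchor
    channel_names: tuple[str, ...]
    anchor: int = 0
    coverage: np.ndarray | None = None  # bool (H, W): pixels covered by >= 1 tile

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


@dataclass(frozen=True)
class PairShift:
    """Residual (dy, dx) correction to a nominal inter-tile offset."""

    dy: float
    dx: float
    confidence: float
    reliable: bool


# ---------------------------------------------------------------------------
# Patch grid + AIF fusion
# ---------------------------------------------------------------------------


def _starts(n: int, size: int, step: int) -> list[int]:
    if size >= n:
        return [0]
    s = list(range(0, n - size + 1, step))
    if s[-1] != n - size:
        s.append(n - size)
    return s


def split_patches(
    shape: tuple[int, int], patch_size_px: int = 600, patch_overlap_px: int = 50
) -> list[tuple[int, int, int, int]]:
    """Grid of (y0, y1, x0, x1) windows covering ``shape`` exactly.

    Interior windows are ``patch_size_px`` square and adjacent windows share
    at least ``patch_overlap_px``; windows at the far edge are shifted back
    to end on the boundary (a tile smaller than the patch yields one clamped
    window).
    """
    if patch_overlap_px >= patch_size_px:
        raise ValueError("patch overlap must be smaller than the patch size")
    if patch_overlap_px < 0:
        raise ValueError("patch overlap must be >= 0")
    h, w = shape
    step = patch_size_px - patch_overlap_px
    wins = []
    for y0 in _starts(h, patch_size_px, step):
        for x0 in _starts(w, patch_size_px, step):
            wins.append((y0, min(y0 + patch_size_px, h), x0, min(x0 + patch_size_px, w)))
    return wins


def _feather_weight(h: int, w: int, feather_px: int) -> np.ndarray:
    """Linear ramp from the window border inward over ``feather_px``."""
    if feather_px <= 0:
        return np.ones((h, w))
    ry = np.minimum(np.arange(h) + 1, np.arange(h)[::-1] + 1)
    rx = np.minimum(np.arange(w) + 1, np.arange(w)[::-1] + 1)
    wy = np.clip(ry / (feather_px + 1), None, 1.0)
    wx = np.clip(rx / (feather_px + 1), None, 1.0)
    return np.outer(wy, wx)


def fuse_aif(tile: ZStackTile, patch_size_px: int = 600, patch_overlap_px: int = 50) -> AifTile:
    """Compress a z-stack into an all-in-focus tile.

    For every channel and patch window, the z-slice maximizing the patch
    Tenengrad is selected; overlapping patches are blended with linear
    feathering.  With zero patch overlap the fusion is an exact per-patch
    copy of the selected slice.
    """
    c, nz, h, w = tile.data.shape
    if nz < 1:
        raise ValueError("need at least one z plane")
    wins = split_patches((h, w), min(patch_size_px, h, w), patch_overlap_px)
    ys = sorted({win[0] for win in wins})
    xs = sorted({win[2] for win in wins})
    choice = np.zeros((c, len(ys), len(xs)), dtype=int)
    out = np.zeros((c, h, w))
    for ci in range(c):
        acc = np.zeros((h, w))
        accw = np.zeros((h, w))
        for (y0, y1, x0, x1) in wins:
            if nz == 1:
                zi = 0
            else:
                scores = [tenengrad(tile.data[ci, z, y0:y1, x0:x1]) for z in range(nz)]
                zi = int(np.argmax(scores))
            choice[ci, ys.index(y0), xs.index(x0)] = zi
            wgt = _feather_weight(y1 - y0, x1 - x0, patch_overlap_px)
            acc[y0:y1, x0:x1] += wgt * tile.data[ci, zi, y0:y1, x0:x1]
            accw[y0:y1, x0:x1] += wgt
        out[ci] = acc / np.maximum(accw, 1e-12)
    return AifTile(out, tile.stage_xy_um, tile.channel_names, choice)


# ---------------------------------------------------------------------------
# Shading correction
# ---------------------------------------------------------------------------


def estimate_flatfield(tiles: Sequence[AifTile], smoothing_sigma_px: float = 25.0) -> np.ndarray:
    """Retrospective flat-field: per-pixel median across tiles, Gaussian
    smoothed and normalized to mean 1 per channel.  Strictly positive.

    Scale-equivariant: multiplying every tile by a constant leaves the
    estimate unchanged.
    """
    if len(tiles) < 3:
        raise ValueError("flat-field estimation needs at least 3 tiles")
    stack = np.stack([t.data for t in tiles])  # (n, c, h, w)
    med = np.median(stack, axis=0)
    field = np.empty_like(med)
    for ci in range(med.shape[0]):
        sm = ndimage.gaussian_filter(med[ci], smoothing_sigma_px, mode="reflect")
        mean = sm.mean()
        if mean <= 0:
            field[ci] = 1.0
        else:
            field[ci] = np.maximum(sm / mean, 1e-3)
            field[ci] /= field[ci].mean()
    return field


def apply_flatfield(tile: AifTile, field: np.ndarray) -> AifTile:
    """Divide out the shading field (pixel-wise), clipping to [0, 1]."""
    if field.shape != tile.data.shape:
        raise ValueError("field shape must match tile data shape")
    if np.any(field <= 0):
        raise ValueError("flat field must be strictly positive")
    return AifTile(np.clip(tile.data / field, 0.0, 1.0), tile.stage_xy_um, tile.channel_names, tile.z_choice_map)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


def _as_channel_image(tile, channel: str) -> np.ndarray:
    if isinstance(tile, AifTile):
        return tile.channel(channel)
    return np.asarray(tile, float)


def _phase_peak(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized phase-correlation peak magnitude in [0, 1]."""
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    r = fa * np.conj(fb)
    denom = np.abs(r)
    r = np.where(denom > 1e-12, r / np.maximum(denom, 1e-12), 0.0)
    return float(np.abs(np.fft.ifft2(r)).max())


def register_pair(
    tile_a,
    tile_b,
    nominal_offset_px: tuple[float, float],
    upsample_factor: int = 20,
    channel: str = "DAPI",
    min_overlap_px: int = 64,
    confidence_floor: float = 0.03,
    max_residual_px: float = 16.0,
) -> PairShift:
    """Subpixel residual shift between two adjacent tiles.

    ``nominal_offset_px`` is tile_b's origin relative to tile_a's, (dy, dx).
    Phase correlation runs on the nominal overlap strips and is refined by
    Fourier-domain upsampling to ``1/upsample_factor`` px.  The true offset
    is ``nominal + (dy, dx)`` of the returned shift.  A too-small overlap, a
    phase-correlation peak below the confidence floor, or a residual beyond
    ``max_residual_px`` (stage repeatability bound — larger peaks are
    spurious matches between different cells in a sparse strip) returns the
    nominal offset (zero residual) flagged unreliable.
    """
    a = _as_channel_image(tile_a, channel)
    b = _as_channel_image(tile_b, channel)
    ha, wa = a.shape
    hb, wb = b.shape
    dy, dx = nominal_offset_px
    idy, idx = int(round(dy)), int(round(dx))
    ya0, ya1 = max(idy, 0), min(ha, idy + hb)
    xa0, xa1 = max(idx, 0), min(wa, idx + wb)
    if (ya1 - ya0) < 3 or (xa1 - xa0) < 3 or max(ya1 - ya0, xa1 - xa0) < min_overlap_px:
        return PairShift(0.0, 0.0, 0.0, False)
    strip_a = a[ya0:ya1, xa0:xa1]
    strip_b = b[ya0 - idy : ya1 - idy, xa0 - idx : xa1 - idx]
    # Hann window suppresses the spectral leakage of the strip borders,
    # which otherwise dominates narrow overlap strips
    win = np.outer(np.hanning(strip_a.shape[0]), np.hanning(strip_a.shape[1]))
    wa = (strip_a - strip_a.mean()) * win
    wb = (strip_b - strip_b.mean()) * win
    conf = _phase_peak(wa, wb)
    if conf < confidence_floor:
        return PairShift(0.0, 0.0, conf, False)
    shift, _, _ = phase_cross_correlation(
        wa, wb, upsample_factor=upsample_factor, normalization="phase"
    )
    # strip_b(p) = strip_a(p + r) when the true offset is nominal + r, and
    # phase correlation returns exactly that r
    r_dy, r_dx = float(shift[0]) + (idy - dy), float(shift[1]) + (idx - dx)
    if max(abs(r_dy), abs(r_dx)) > max_residual_px:
        return PairShift(0.0, 0.0, conf, False)
    return PairShift(r_dy, r_dx, conf, True)


def register_grid(
    tiles: Sequence[AifTile],
    grid_shape: tuple[int, int],
    tile_shape_px: tuple[int, int],
    tile_overlap_px: int,
    upsample_factor: int = 20,
    channel: str = "DAPI",
    min_overlap_px: int = 16,
    max_residual_px: float = 16.0,
) -> dict[tuple[int, int], PairShift]:
    """Measure the residual shift for every row-major chain pair:
    left neighbor for column 0 is the tile above; otherwise the tile to the
    left.  Keys are flat tile indices ``(parent, child)``."""
    rows, cols = grid_shape
    h, w = tile_shape_px
    shifts: dict[tuple[int, int], PairShift] = {}
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if (r, c) == (0, 0):
                continue
            if c > 0:
                parent = i - 1
                nominal = (0.0, float(w - tile_overlap_px))
            else:
                parent = i - cols
                nominal = (float(h - tile_overlap_px), 0.0)
            shifts[(parent, i)] = register_pair(
                tiles[parent], tiles[i], nominal,
                upsample_factor=upsample_factor, channel=channel,
                min_overlap_px=min_overlap_px, max_residual_px=max_residual_px,
            )
    return shifts


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------


def _fourier_translate(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Subpixel translation by Fourier shift, reflection-padded to suppress
    wraparound."""
    p = EDGE_TAPER_PX
    padded = np.pad(img, p, mode="reflect")
    f = np.fft.fft2(padded)
    shifted = np.fft.ifft2(ndimage.fourier_shift(f, (dy, dx))).real
    return shifted[p:-p, p:-p]


def stitch(
    tiles: Sequence[AifTile],
    grid_shape: tuple[int, int],
    tile_shape_px: tuple[int, int],
    tile_overlap_px: int,
    pairwise_shifts: dict[tuple[int, int], PairShift],
) -> AifMosaic:
    """Accumulate global offsets from the upper-left anchor along the
    row-major chain and blend subpixel-translated tiles with
    distance-transform-to-border weights."""
    rows, cols = grid_shape
    if len(tiles) != rows * cols:
        raise ValueError("tile count does not match grid shape")
    h, w = tile_shape_px
    step_y, step_x = h - tile_overlap_px, w - tile_overlap_px
    offsets = np.zeros((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if (r, c) == (0, 0):
                continue
            if c > 0:
                parent, nominal = i - 1, (0.0, float(step_x))
            else:
                parent, nominal = i - cols, (float(step_y), 0.0)
            key = (parent, i)
            if key not in pairwise_shifts:
                raise ValueError(f"tile {i} is not connected to the anchor (missing pair {key})")
            s = pairwise_shifts[key]
            offsets[i] = offsets[parent] + np.array(nominal) + np.array([s.dy, s.dx])

    n_ch = tiles[0].data.shape[0]
    oy = offsets[:, 0] - offsets[:, 0].min()
    ox = offsets[:, 1] - offsets[:, 1].min()
    H = int(np.ceil(oy.max())) + h
    W = int(np.ceil(ox.max())) + w
    acc = np.zeros((n_ch, H, W))
    accw = np.zeros((H, W))

    # distance of each tile pixel to the tile border (>= 1 everywhere)
    base_weight = ndimage.distance_transform_edt(np.pad(np.ones((h, w)), 1))[1:-1, 1:-1]

    for i, tile in enumerate(tiles):
        iy, ix = int(np.floor(oy[i])), int(np.floor(ox[i]))
        fy, fx = oy[i] - iy, ox[i] - ix
        for ci in range(n_ch):
            img = tile.data[ci]
            if fy != 0 or fx != 0:
                img = _fourier_translate(img, fy, fx)
            acc[ci, iy : iy + h, ix : ix + w] += base_weight * np.clip(img, 0, 1)
        accw[iy : iy + h, ix : ix + w] += base_weight
    covered = accw > 0
    data = acc / np.maximum(accw, 1e-12)[None]
    rel = offsets - offsets[0]
    return AifMosaic(data, rel, tiles[0].channel_names, anchor=0, coverage=covered)


def write_mosaic(mosaic: AifMosaic, path: str | Path, offsets_csv: str | Path | None = None) -> None:
    """Mosaic as a multi-page TIFF (one page per channel) plus offsets CSV."""
    tifffile.imwrite(Path(path), mosaic.data.astype(np.float32))
    if offsets_csv is not None:
        pd.DataFrame(
            dict(
                tile_id=np.arange(len(mosaic.tile_offsets_px)),
                dy_px=mosaic.tile_offsets_px[:, 0],
                dx_px=mosaic.tile_offsets_px[:, 1],
            )
        ).to_csv(offsets_csv, index=False)
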