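"""Synthetic microfilter scene simulation.

Generates wavy-membrane slide scenes populated with tumor cells (mCTC:
DAPI+/CK+), cancer-associated fibroblasts (CAF: DAPI+/FAP+), hollow filter
pores and fluorophore precipitates, and renders them as multi-channel,
multi-z defocus-blurred image tiles with pixel-exact ground truth.

Conventions
-----------
* Pixel coordinates are 0-based, ``(row=y, col=x)``; boxes are half-open
  ``[x_min, x_max) x [y_min, y_max)``.
* Stage coordinates are in micrometres, +x right, +y down; ``stage_xy_um``
  is the position of a tile's top-left pixel.
* z increases toward the objective; an object at height ``z`` is in focus
  when the scan plane equals ``z`` (plus any chromatic offset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.special import erfc

__all__ = [
    "CHANNELS",
    "HeightField",
    "SceneObject",
    "GroundTruthScene",
    "OpticsModel",
    "ZStackTile",
    "PlacementError",
    "generate_surface",
    "populate_scene",
    "render_plane",
    "render_ideal_plane",
    "render_tile",
    "render_wsi_scan",
    "ground_truth_boxes",
    "write_tile",
    "read_tile",
    "write_ground_truth",
]

#: Default channel order: nuclear stain, epithelial marker, fibroblast marker.
CHANNELS: tuple[str, ...] = ("DAPI", "CK", "FAP")

#: Intrinsic (in-focus) edge softness of a stained cell boundary, px.
EDGE_SIGMA_PX = 1.0

CELL_CLASSES = ("mCTC", "CAF")
OBJECT_CLASSES = ("mCTC", "CAF", "pore", "precipitate")


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed under the min-distance constraint."""


# ---------------------------------------------------------------------------
# Membrane surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeightField:
    """Smooth random membrane surface height map (µm) over the slide area."""

    heights: np.ndarray
    pixel_pitch_um: float
    amplitude_um: float
    correlation_length_um: float
    seed: int

    def at(self, x_um, y_um):
        """Bilinear-interpolated surface height (µm) at slide coordinates."""
        gy = np.clip(np.asarray(y_um, float) / self.pixel_pitch_um, 0, self.heights.shape[0] - 1)
        gx = np.clip(np.asarray(x_um, float) / self.pixel_pitch_um, 0, self.heights.shape[1] - 1)
        return ndimage.map_coordinates(self.heights, [np.atleast_1d(gy), np.atleast_1d(gx)], order=1)


def generate_surface(
    extent_um: float | tuple[float, float],
    amplitude_um: float = 15.0,
    correlation_length_um: float = 500.0,
    pixel_pitch_um: float = 5.0,
    seed: int = 0,
) -> HeightField:
    """Band-limited random surface: white noise, Gaussian low-pass at the
    correlation length, rescaled so the sample standard deviation equals
    ``amplitude_um``.  Deterministic per seed.
    """
    if np.isscalar(extent_um):
        extent_um = (float(extent_um), float(extent_um))
    ex, ey = float(extent_um[0]), float(extent_um[1])
    if ex <= 0 or ey <= 0:
        raise ValueError(f"extent must be positive, got {extent_um}")
    if amplitude_um < 0:
        raise ValueError("amplitude must be non-negative")
    if correlation_length_um <= 0 or pixel_pitch_um <= 0:
        raise ValueError("correlation length and pixel pitch must be positive")

    nx = max(int(np.ceil(ex / pixel_pitch_um)) + 1, 2)
    ny = max(int(np.ceil(ey / pixel_pitch_um)) + 1, 2)
    if amplitude_um == 0:
        heights = np.zeros((ny, nx))
    else:
        rng = np.random.default_rng(seed)
        sigma = correlation_length_um / pixel_pitch_um
        # pad by the kernel radius so every retained point sees full
        # support of genuine iid noise, then rescale by the analytic std of
        # Gaussian-filtered unit white noise (sum of squared kernel
        # weights).  The process std then equals the amplitude regardless
        # of field extent: a field smaller than the correlation length is a
        # nearly flat surface at a random offset, not a renormalized rough
        # one.
        r = int(max(4.0 * sigma + 0.5, 1))
        noise = rng.standard_normal((ny + 2 * r, nx + 2 * r))
        smooth = ndimage.gaussian_filter(noise, sigma, mode="constant", truncate=4.0)
        smooth = smooth[r : r + ny, r : r + nx]
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
        k /= k.sum()
        std = float((k**2).sum())  # per-axis second moment; 2-D std equals it
        heights = smooth * (amplitude_um / std)
    return HeightField(heights, pixel_pitch_um, amplitude_um, correlation_length_um, seed)


# ---------------------------------------------------------------------------
# Scene population
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneObject:
    """One simulated object on the membrane."""

    id: int
    cls: str
    x_um: float
    y_um: float
    z_um: float
    diameter_um: float
    channel_intensity: Mapping[str, float]
    eccentricity: float = 0.0
    angle_rad: float = 0.0
    ring_width_um: float = 0.0  # > 0 for hollow pores (annulus)


@dataclass(frozen=True)
class GroundTruthScene:
    """Simulated slide: object records plus the surface they sit on."""

    objects: tuple[SceneObject, ...]
    slide_extent_um: tuple[float, float]
    surface: HeightField
    seed: int

    def of_class(self, cls: str) -> list[SceneObject]:
        return [o for o in self.objects if o.cls == cls]


DEFAULT_INTENSITY = {
    # class -> (channel -> (mean peak amplitude, relative jitter))
    "mCTC": {"DAPI": (0.75, 0.1), "CK": (0.85, 0.1)},
    "CAF": {"DAPI": (0.75, 0.1), "FAP": (0.80, 0.1)},
    # pores get a faint ring in exactly ONE of CK/FAP (chosen per pore) so
    # marker exclusivity holds for every object
    "pore": {"ring": (0.30, 0.2)},
    "precipitate": {"spot": (0.70, 0.2)},
}

DEFAULT_DIAMETER_UM = {
    "mCTC": (15.0, 1.5, 10.0, 20.0),  # mean, sd, lo, hi
    "CAF": (20.0, 3.0, 12.0, 30.0),
    "pore": (8.0, 0.5, 6.5, 9.5),
    "precipitate": (2.5, 0.8, 1.0, 5.0),
}


def _draw_diameter(rng, cls):
    mean, sd, lo, hi = DEFAULT_DIAMETER_UM[cls]
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _jittered(rng, mean, rel):
    return float(np.clip(rng.normal(mean, rel * mean), 0.05, 1.0))


def populate_scene(
    surface: HeightField,
    n_mctc: int,
    n_caf: int,
    n_pore: int = 0,
    n_precip: int = 0,
    seed: int = 0,
    intensity_config: Mapping | None = None,
    min_distance_um: float = 25.0,
    margin_um: float = 12.0,
    max_retries: int = 500,
) -> GroundTruthScene:
    """Place objects uniformly at random with a minimum center distance.

    The distance constraint applies between cells and pores (``min_distance_um
    = 0`` permits clumps); precipitates are unconstrained debris.  Each
    object's z is read off the surface at its center.  mCTCs carry CK but no
    FAP; CAFs the reverse; pores have zero DAPI interior (hollow).
    """
    for name, n in (("n_mctc", n_mctc), ("n_caf", n_caf), ("n_pore", n_pore), ("n_precip", n_precip)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    cfg = dict(DEFAULT_INTENSITY)
    if intensity_config:
        cfg.update(intensity_config)

    ny, nx = surface.heights.shape
    ex = (nx - 1) * surface.pixel_pitch_um
    ey = (ny - 1) * surface.pixel_pitch_um
    lo_x, hi_x = margin_um, max(ex - margin_um, margin_um)
    lo_y, hi_y = margin_um, max(ey - margin_um, margin_um)

    rng = np.random.default_rng(seed)
    placed_xy: list[tuple[float, float]] = []
    objects: list[SceneObject] = []
    oid = 0

    def place(constrained: bool) -> tuple[float, float]:
        for _ in range(max_retries):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if not constrained or min_distance_um <= 0 or not placed_xy:
                return x, y
            pts = np.asarray(placed_xy)
            if np.min((x - pts[:, 0]) ** 2 + (y - pts[:, 1]) ** 2) >= min_distance_um**2:
                return x, y
        raise PlacementError(
            f"could not place object {oid} with min distance {min_distance_um} µm "
            f"after {max_retries} attempts (area {ex:.0f}x{ey:.0f} µm)"
        )

    for cls, n in (("mCTC", n_mctc), ("CAF", n_caf), ("pore", n_pore)):
        for _ in range(n):
            x, y = place(constrained=True)
            placed_xy.append((x, y))
            z = float(surface.at(x, y)[0])
            d = _draw_diameter(rng, cls)
            if cls == "pore":
                ring_ch = "CK" if rng.random() < 0.5 else "FAP"
                mean, rel = cfg["pore"]["ring"]
                inten = {ring_ch: _jittered(rng, mean, rel)}
                obj = SceneObject(oid, cls, x, y, z, d, inten, ring_width_um=1.5)
            else:
                inten = {ch: _jittered(rng, m, r) for ch, (m, r) in cfg[cls].items()}
                ecc = float(rng.uniform(0.0, 0.8)) if cls == "CAF" else 0.0
                ang = float(rng.uniform(0, np.pi)) if cls == "CAF" else 0.0
                obj = SceneObject(oid, cls, x, y, z, d, inten, eccentricity=ecc, angle_rad=ang)
            objects.append(obj)
            oid += 1

    for _ in range(n_precip):
        x, y = place(constrained=False)
        z = float(surface.at(x, y)[0])
        d = _draw_diameter(rng, "precipitate")
        ch = "CK" if rng.random() < 0.5 else "FAP"
        mean, rel = cfg["precipitate"]["spot"]
        objects.append(SceneObject(oid, "precipitate", x, y, z, d, {ch: _jittered(rng, mean, rel)}))
        oid += 1

    return GroundTruthScene(tuple(objects), (ex, ey), surface, seed)


# ---------------------------------------------------------------------------
# Optics
# ---------------------------------------------------------------------------


def _default_wavelengths():
    return {"DAPI": 0.46, "CK": 0.52, "FAP": 0.62}


def _zero_offsets():
    return {"DAPI": 0.0, "CK": 0.0, "FAP": 0.0}


@dataclass(frozen=True)
class OpticsModel:
    """Imaging model: 20x/0.4 NA epifluorescence objective defaults.

    Defocus maps to a Gaussian blur of sigma
    ``max(blur_sigma_min_px, k * |defocus| / pixel_size)`` where ``k`` is
    calibrated so sigma is ~1.5 px at one depth of field.
    """

    na: float = 0.4
    wavelength_um: Mapping[str, float] = field(default_factory=_default_wavelengths)
    pixel_size_um: float = 0.23
    chromatic_offset_um: Mapping[str, float] = field(default_factory=_zero_offsets)
    vignetting_strength: float = 0.15
    background: float = 0.03
    noise_gaussian_sigma: float = 0.003
    noise_poisson_scale: float = 2000.0
    blur_sigma_min_px: float = 0.4
    blur_coeff: float | None = None  # k; derived from DOF when None
    reference_wavelength_um: float = 0.55

    def depth_of_field_um(self, wavelength_um: float | None = None) -> float:
        lam = self.reference_wavelength_um if wavelength_um is None else wavelength_um
        return lam / (2.0 * self.na**2)

    @property
    def k(self) -> float:
        if self.blur_coeff is not None:
            return self.blur_coeff
        return 1.5 * self.pixel_size_um / self.depth_of_field_um()

    def blur_sigma_px(self, defocus_um) -> np.ndarray:
        d = np.abs(np.asarray(defocus_um, float))
        return np.maximum(self.blur_sigma_min_px, self.k * d / self.pixel_size_um)

    def noiseless(self) -> "OpticsModel":
        return replace(self, noise_gaussian_sigma=0.0, noise_poisson_scale=0.0)

    def clean(self) -> "OpticsModel":
        """Noise and vignetting off — for oracle renders."""
        return replace(
            self, noise_gaussian_sigma=0.0, noise_poisson_scale=0.0, vignetting_strength=0.0
        )


# ---------------------------------------------------------------------------
# Tile container
# ---------------------------------------------------------------------------


@dataclass
class ZStackTile:
    """One lateral field of view: channels x z-planes x rows x cols volume."""

    data: np.ndarray
    z_positions_um: np.ndarray
    stage_xy_um: tuple[float, float]
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.z_positions_um = np.asarray(self.z_positions_um, float)
        if self.data.ndim != 4:
            raise ValueError("data must be (channels, z, rows, cols)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count mismatch")
        if self.data.shape[1] != len(self.z_positions_um):
            raise ValueError("n_z must equal len(z_positions_um)")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if np.any(np.diff(self.z_positions_um) <= 0):
            raise ValueError("z positions must be strictly increasing")

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in {self.channel_names}") from None

    def plane(self, channel: str, z_index: int) -> np.ndarray:
        return self.data[self.channel_index(channel), z_index]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _soft_disc(rho_px: np.ndarray, radius_px: float, sigma_px: float) -> np.ndarray:
    """Radial profile of a unit disc convolved with a Gaussian.

    The erf edge model is exact in the sharp limit (sigma << radius); its
    center value is renormalized to the exact ``1 - exp(-r^2 / 2 sigma^2)``
    so that strongly defocused objects fade into the background instead of
    plateauing at half amplitude (energy must spread, not grow).
    """
    s = np.sqrt(2.0) * sigma_px
    prof = 0.5 * erfc((rho_px - radius_px) / s)
    center = 0.5 * erfc(-radius_px / s)
    exact_center = 1.0 - np.exp(-(radius_px**2) / (2.0 * sigma_px**2))
    return prof * (exact_center / center)


def _object_footprint(obj: SceneObject, optics: OpticsModel, channel: str, sigma_px: float):
    """Max extent (px) of the rendered object, and per-channel amplitude."""
    amp = obj.channel_intensity.get(channel, 0.0)
    r_px = 0.5 * obj.diameter_um / optics.pixel_size_um
    if obj.cls in CELL_CLASSES and channel == "DAPI":
        r_px *= 0.6  # nucleus
    return r_px, amp


def _render_object(plane, obj, optics, channel, cx, cy, sigma_blur_px):
    r_px, amp = _object_footprint(obj, optics, channel, sigma_blur_px)
    if amp <= 0:
        return
    sigma = float(np.hypot(sigma_blur_px, EDGE_SIGMA_PX))
    # ellipse semi-axes (a >= b); circles when eccentricity == 0
    a = r_px
    b = r_px * np.sqrt(1.0 - obj.eccentricity**2)
    r_eff = np.sqrt(a * b)
    ext = int(np.ceil(a + 4.0 * sigma + 2))
    h, w = plane.shape
    x0, x1 = int(np.floor(cx)) - ext, int(np.floor(cx)) + ext + 1
    y0, y1 = int(np.floor(cy)) - ext, int(np.floor(cy)) + ext + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    u = xx - cx
    v = yy - cy
    if obj.eccentricity > 0:
        ca, sa = np.cos(obj.angle_rad), np.sin(obj.angle_rad)
        up = u * ca + v * sa
        vp = -u * sa + v * ca
        m = np.sqrt((up / a) ** 2 + (vp / b) ** 2 + 1e-12)
        rho = m * r_eff
        radius = r_eff
    else:
        rho = np.sqrt(u**2 + v**2)
        radius = r_px
    if obj.ring_width_um > 0:  # hollow pore: annulus
        w_px = obj.ring_width_um / optics.pixel_size_um
        prof = _soft_disc(rho, radius, sigma) - _soft_disc(rho, radius - w_px, sigma)
    else:
        prof = _soft_disc(rho, radius, sigma)
    plane[y0c:y1c, x0c:x1c] += amp * prof


def _vignette(shape_px, strength):
    h, w = shape_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (cx**2 + cy**2 + 1e-12)
    return 1.0 - strength * r2


def _plane_rng(scene_seed, channel, z_um, stage_xy_um):
    key = [
        int(scene_seed) & 0x7FFFFFFF,
        abs(hash(channel)) & 0x7FFFFFFF,
        int(round(z_um * 1000)) & 0x7FFFFFFF,
        int(round(stage_xy_um[0] * 1000)) & 0x7FFFFFFF,
        int(round(stage_xy_um[1] * 1000)) & 0x7FFFFFFF,
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def render_plane(
    scene: GroundTruthScene,
    optics: OpticsModel,
    stage_xy_um: tuple[float, float],
    shape_px: tuple[int, int],
    z_um: float,
    channel: str,
    apply_noise: bool = True,
) -> np.ndarray:
    """Render one (stage position, z, channel) plane of the scene.

    Each in-view object is drawn as a soft-edged disc (pores: annulus)
    blurred according to its defocus ``|z - z_obj - chromatic_offset|``,
    then vignetting, background and noise are applied and the result is
    clipped to [0, 1].
    """
    if channel not in set(CHANNELS) | {k for o in scene.objects for k in o.channel_intensity}:
        if channel not in CHANNELS:
            raise KeyError(f"unknown channel {channel!r}")
    h, w = shape_px
    plane = np.zeros((h, w))
    sx, sy = stage_xy_um
    off = optics.chromatic_offset_um.get(channel, 0.0)
    for obj in scene.objects:
        amp = obj.channel_intensity.get(channel, 0.0)
        if amp <= 0:
            continue
        defocus = z_um - obj.z_um - off
        sigma_blur = float(optics.blur_sigma_px(defocus))
        cx = (obj.x_um - sx) / optics.pixel_size_um
        cy = (obj.y_um - sy) / optics.pixel_size_um
        ext_um = 0.5 * obj.diameter_um + (4 * sigma_blur + 6) * optics.pixel_size_um
        ext_px = ext_um / optics.pixel_size_um
        if cx < -ext_px or cx > w + ext_px or cy < -ext_px or cy > h + ext_px:
            continue
        _render_object(plane, obj, optics, channel, cx, cy, sigma_blur)
    plane += optics.background
    if optics.vignetting_strength > 0:
        plane *= _vignette(shape_px, optics.vignetting_strength)
    if apply_noise and (optics.noise_poisson_scale > 0 or optics.noise_gaussian_sigma > 0):
        rng = _plane_rng(scene.seed, channel, z_um, stage_xy_um)
        if optics.noise_poisson_scale > 0:
            plane = rng.poisson(np.clip(plane, 0, None) * optics.noise_poisson_scale) / optics.noise_poisson_scale
        if optics.noise_gaussian_sigma > 0:
            plane = plane + rng.normal(0.0, optics.noise_gaussian_sigma, plane.shape)
    return np.clip(plane, 0.0, 1.0)


def render_ideal_plane(
    scene: GroundTruthScene,
    optics: OpticsModel,
    stage_xy_um: tuple[float, float],
    shape_px: tuple[int, int],
    channel: str,
) -> np.ndarray:
    """All-in-focus oracle: every object rendered at zero defocus, no
    vignetting or noise.  Serves as ground truth for stitching/AIF tests."""
    h, w = shape_px
    plane = np.zeros((h, w))
    sx, sy = stage_xy_um
    for obj in scene.objects:
        amp = obj.channel_intensity.get(channel, 0.0)
        if amp <= 0:
            continue
        cx = (obj.x_um - sx) / optics.pixel_size_um
        cy = (obj.y_um - sy) / optics.pixel_size_um
        ext_px = 0.5 * obj.diameter_um / optics.pixel_size_um + 10
        if cx < -ext_px or cx > w + ext_px or cy < -ext_px or cy > h + ext_px:
            continue
        _render_object(plane, obj, optics, channel, cx, cy, optics.blur_sigma_min_px)
    plane += optics.background
    return np.clip(plane, 0.0, 1.0)


def render_tile(
    scene: GroundTruthScene,
    optics: OpticsModel,
    stage_xy_um: tuple[float, float],
    tile_shape_px: tuple[int, int],
    z_positions_um: Sequence[float],
    channel_names: tuple[str, ...] = CHANNELS,
    apply_noise: bool = True,
) -> ZStackTile:
    """Render a full multi-channel z-stack tile at one stage position."""
    z = np.asarray(z_positions_um, float)
    if z.ndim != 1 or len(z) < 1 or np.any(np.diff(z) <= 0):
        raise ValueError("z_positions_um must be 1-D strictly increasing")
    h, w = tile_shape_px
    if h <= 0 or w <= 0:
        raise ValueError("tile shape must be positive")
    data = np.empty((len(channel_names), len(z), h, w))
    for ci, ch in enumerate(channel_names):
        for zi, zv in enumerate(z):
            data[ci, zi] = render_plane(scene, optics, stage_xy_um, (h, w), zv, ch, apply_noise)
    return ZStackTile(data, z, tuple(stage_xy_um), tuple(channel_names))


def render_wsi_scan(
    scene: GroundTruthScene,
    optics: OpticsModel,
    scan_grid: tuple[int, int],
    tile_shape_px: tuple[int, int],
    tile_overlap_px: int,
    z_positions_um: Sequence[float],
    stage_jitter_px: float = 0.5,
    tilt_rad: float = 0.001,
    seed: int = 0,
    channel_names: tuple[str, ...] = CHANNELS,
    apply_noise: bool = True,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> tuple[list[ZStackTile], np.ndarray]:
    """Row-major grid scan with nominal tile overlap.

    True tile positions are perturbed by sub-pixel stage jitter and a small
    global rotation between stage and camera axes, so registration is
    non-trivial.  Tiles carry their *nominal* stage position; the returned
    array holds the true pixel offsets ``(rows, cols, 2) -> (dy, dx)`` of
    each tile's origin relative to the anchor, the stitching ground truth.
    """
    rows, cols = scan_grid
    h, w = tile_shape_px
    if tile_overlap_px >= min(h, w):
        raise ValueError("tile overlap must be smaller than the tile")
    rng = np.random.default_rng(seed)
    step_y, step_x = h - tile_overlap_px, w - tile_overlap_px
    ct, st = np.cos(tilt_rad), np.sin(tilt_rad)

    tiles: list[ZStackTile] = []
    true_offsets = np.zeros((rows, cols, 2))
    for r in range(rows):
        for c in range(cols):
            ny_px, nx_px = r * step_y, c * step_x  # nominal, px
            # stage axes rotated by tilt relative to camera frame
            tx = ct * nx_px - st * ny_px
            ty = st * nx_px + ct * ny_px
            if (r, c) != (0, 0) and stage_jitter_px > 0:
                tx += rng.uniform(-stage_jitter_px, stage_jitter_px)
                ty += rng.uniform(-stage_jitter_px, stage_jitter_px)
            if (r, c) == (0, 0):
                tx, ty = 0.0, 0.0  # anchor defines the frame
            true_offsets[r, c] = (ty, tx)
            true_xy_um = (
                origin_um[0] + tx * optics.pixel_size_um,
                origin_um[1] + ty * optics.pixel_size_um,
            )
            tile = render_tile(
                scene, optics, true_xy_um, tile_shape_px, z_positions_um, channel_names, apply_noise
            )
            # scanner's belief: the nominal grid position
            tile.stage_xy_um = (
                origin_um[0] + nx_px * optics.pixel_size_um,
                origin_um[1] + ny_px * optics.pixel_size_um,
            )
            tiles.append(tile)
    return tiles, true_offsets


# ---------------------------------------------------------------------------
# Ground-truth export
# ---------------------------------------------------------------------------


def _bbox_half_extents_px(obj: SceneObject, pixel_size_um: float) -> tuple[float, float]:
    a = 0.5 * obj.diameter_um / pixel_size_um
    b = a * np.sqrt(1.0 - obj.eccentricity**2)
    if obj.eccentricity == 0:
        return a, a
    ca, sa = np.cos(obj.angle_rad), np.sin(obj.angle_rad)
    hx = np.sqrt((a * ca) ** 2 + (b * sa) ** 2)
    hy = np.sqrt((a * sa) ** 2 + (b * ca) ** 2)
    return hx, hy


def ground_truth_boxes(
    scene: GroundTruthScene,
    pixel_size_um: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
    image_shape_px: tuple[int, int] | None = None,
    classes: Sequence[str] = CELL_CLASSES,
) -> pd.DataFrame:
    """Pixel-frame bounding boxes (half-open) of cell objects.

    Boxes are clipped to ``image_shape_px`` when given; objects entirely
    outside the frame are dropped.
    """
    rows = []
    for obj in scene.objects:
        if obj.cls not in classes:
            continue
        cx = (obj.x_um - origin_um[0]) / pixel_size_um
        cy = (obj.y_um - origin_um[1]) / pixel_size_um
        hx, hy = _bbox_half_extents_px(obj, pixel_size_um)
        x0, x1 = cx - hx, cx + hx
        y0, y1 = cy - hy, cy + hy
        if image_shape_px is not None:
            h, w = image_shape_px
            x0, x1 = max(x0, 0.0), min(x1, float(w))
            y0, y1 = max(y0, 0.0), min(y1, float(h))
            if x0 >= x1 or y0 >= y1:
                continue
        rows.append(
            dict(
                id=obj.id,
                label=obj.cls,
                x_min=int(np.floor(x0)),
                y_min=int(np.floor(y0)),
                x_max=int(np.ceil(x1)),
                y_max=int(np.ceil(y1)),
            )
        )
    return pd.DataFrame(rows, columns=["id", "label", "x_min", "y_min", "x_max", "y_max"])


# ---------------------------------------------------------------------------
# I/O: TIFF + JSON sidecar, ground-truth CSV
# ---------------------------------------------------------------------------


def write_tile(tile: ZStackTile, path: str | Path) -> None:
    """One multi-page TIFF per tile (pages channel-major, then z) plus a
    JSON sidecar with stage metadata."""
    path = Path(path)
    c, z, h, w = tile.data.shape
    pages = tile.data.reshape(c * z, h, w).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "stage_xy_um": list(tile.stage_xy_um),
        "z_positions_um": [float(v) for v in tile.z_positions_um],
        "channel_names": list(tile.channel_names),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_tile(path: str | Path) -> ZStackTile:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    c = len(meta["channel_names"])
    z = len(meta["z_positions_um"])
    data = np.asarray(pages, float).reshape(c, z, pages.shape[-2], pages.shape[-1])
    return ZStackTile(
        data,
        np.asarray(meta["z_positions_um"], float),
        tuple(meta["stage_xy_um"]),
        tuple(meta["channel_names"]),
    )


def write_ground_truth(scene: GroundTruthScene, path: str | Path) -> None:
    rows = [
        dict(
            id=o.id,
            **{"class": o.cls},
            x_um=o.x_um,
            y_um=o.y_um,
            z_um=o.z_um,
            diameter_um=o.diameter_um,
        )
        for o in scene.objects
    ]
    pd.DataFrame(rows, columns=["id", "class", "x_um", "y_um", "z_um", "diameter_um"]).to_csv(
        path, index=False
    )
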