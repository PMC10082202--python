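"""Coarse-then-fine autofocus: Tenengrad focus measure, Gaussian peak fit.

The scanner first sweeps z coarsely (default 20 µm steps over 200 µm) in
the DAPI channel, computes the Tenengrad focus metric at each plane, fits a
Gaussian to the metric-vs-z curve and takes its peak as the best focus.
A fine scan (default 5 µm steps over 50 µm) is then centered there and the
same z positions are reused for every fluorescence channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .scene_sim import GroundTruthScene, OpticsModel, ZStackTile, render_plane

__all__ = [
    "ScanPlan",
    "FocusCurve",
    "tenengrad",
    "focus_curve",
    "fit_best_focus",
    "plan_fine_scan",
    "autofocus_tile",
    "make_scene_renderer",
    "SceneRenderer",
]


@dataclass(frozen=True)
class ScanPlan:
    """Axial scan parameters (µm); defaults are the 20x/0.4 NA protocol."""

    coarse_step_um: float = 20.0
    coarse_range_um: float = 200.0
    fine_step_um: float = 5.0
    fine_range_um: float = 50.0
    focus_channel: str = "DAPI"

    def __post_init__(self):
        if self.coarse_step_um <= 0 or self.fine_step_um <= 0:
            raise ValueError("step sizes must be positive")
        if self.coarse_range_um < self.coarse_step_um or self.fine_range_um < self.fine_step_um:
            raise ValueError("scan range must be at least one step")

    def coarse_positions(self, center_um: float = 0.0) -> np.ndarray:
        return _symmetric_positions(center_um, self.coarse_range_um, self.coarse_step_um)


@dataclass
class FocusCurve:
    """Focus metric vs z for one tile/channel, with optional Gaussian fit."""

    z_um: np.ndarray
    f_values: np.ndarray
    fit: dict | None = None

    def __post_init__(self):
        self.z_um = np.asarray(self.z_um, float)
        self.f_values = np.asarray(self.f_values, float)
        if len(self.z_um) != len(self.f_values):
            raise ValueError("z and f must have equal length")
        if len(self.z_um) < 3:
            raise ValueError("focus curve needs at least 3 points")
        if np.any(self.f_values < 0):
            raise ValueError("focus values must be non-negative")


def tenengrad(image: np.ndarray, threshold: float = 0.0) -> float:
    """Tenengrad focus measure: sum of squared Sobel gradient magnitude over
    the valid interior (1-px border excluded).

    Invariant under constant offsets and translations; strictly decreases
    under blurring of any non-constant image.  ``threshold`` discards
    squared-magnitude contributions below its value (default 0: plain sum).
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(img.shape) < 3:
        raise ValueError("image must be at least 3x3")
    gx = ndimage.sobel(img, axis=1)
    gy = ndimage.sobel(img, axis=0)
    g2 = (gx**2 + gy**2)[1:-1, 1:-1]
    if threshold > 0:
        g2 = np.where(g2 >= threshold, g2, 0.0)
    return float(g2.sum())


def focus_curve(tile: ZStackTile, channel: str, threshold: float = 0.0) -> FocusCurve:
    """Per-plane Tenengrad over one channel of a z-stack tile (no fit)."""
    ci = tile.channel_index(channel)
    if tile.data.shape[1] < 3:
        raise ValueError("need at least 3 z planes")
    f = np.array([tenengrad(tile.data[ci, zi], threshold) for zi in range(tile.data.shape[1])])
    return FocusCurve(tile.z_positions_um.copy(), f)


def _gaussian(z, amp, mu, sigma, offset):
    return amp * np.exp(-((z - mu) ** 2) / (2.0 * sigma**2)) + offset


def fit_best_focus(
    curve: FocusCurve, coarse_step_um: float | None = None, window_halfwidth: int | None = 2
) -> float:
    """Fit ``A*exp(-(z-mu)^2 / 2 sigma^2) + B`` to the focus curve and return
    the peak position mu (µm).

    The fit is restricted to ``window_halfwidth`` samples on either side of
    the discrete argmax (``None`` fits the whole sequence): far-from-focus
    planes carry only the noise floor of the metric and would otherwise pull
    the peak estimate.  When the argmax sits at either end of the sweep the
    peak is not bracketed; then — and on non-convergence or a fitted peak
    outside the scanned range — the function falls back to the discrete
    argmax (ties broken toward lower z) and records
    ``fit['converged'] = False`` on the curve.
    """
    z, f = curve.z_um, curve.f_values
    if len(z) < 4:
        raise ValueError("Gaussian fit needs at least 4 points")
    step = coarse_step_um if coarse_step_um is not None else float(np.median(np.diff(z)))
    i0 = int(np.argmax(f))  # argmax takes the first (lowest-z) maximum
    fallback = float(z[i0])

    def _fail():
        curve.fit = dict(
            mu_um=fallback, sigma_um=np.nan, amplitude=np.nan, offset=np.nan, converged=False
        )
        return fallback

    if i0 == 0 or i0 == len(z) - 1:
        return _fail()  # monotone curve: peak outside the scanned range
    if window_halfwidth is None:
        lo, hi = 0, len(z)
    else:
        lo, hi = i0 - window_halfwidth, i0 + window_halfwidth + 1
        while hi - lo < 4:  # 4-parameter fit needs 4 points
            lo, hi = lo - 1, hi + 1
        lo, hi = max(lo, 0), min(hi, len(z))
    zz, ff = z[lo:hi], f[lo:hi]
    p0 = [max(f.max() - f.min(), 1e-12), float(z[i0]), step, float(ff.min())]
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gaussian, zz, ff, p0=p0, maxfev=5000, xtol=1e-8)
        amp, mu, sigma, offset = popt
        ok = np.isfinite(mu) and amp > 0 and z.min() <= mu <= z.max()
    except (RuntimeError, ValueError):
        ok = False
    if not ok:
        return _fail()
    curve.fit = dict(
        mu_um=float(mu), sigma_um=float(abs(sigma)), amplitude=float(amp),
        offset=float(offset), converged=True,
    )
    return float(mu)


def _symmetric_positions(center_um: float, range_um: float, step_um: float) -> np.ndarray:
    n = int(np.floor(range_um / step_um + 1e-9)) + 1
    start = center_um - (n - 1) * step_um / 2.0
    return start + step_um * np.arange(n)


def plan_fine_scan(best_z_um: float, plan: ScanPlan) -> np.ndarray:
    """Fine z positions centered on the best focus: ``best_z ± fine_range/2``
    at ``fine_step`` spacing, both ends included when the range divides.
    The same positions are reused for every channel."""
    return _symmetric_positions(best_z_um, plan.fine_range_um, plan.fine_step_um)


#: A renderer the autofocus loop can drive: (stage_xy_um, z_um, channel) -> 2-D plane.
SceneRenderer = Callable[[tuple[float, float], float, str], np.ndarray]


def autofocus_tile(
    renderer: SceneRenderer,
    stage_xy_um: tuple[float, float],
    plan: ScanPlan = ScanPlan(),
    center_um: float = 0.0,
) -> tuple[float, FocusCurve]:
    """Run the coarse autofocus at one lateral position.

    Renders the coarse z sweep in the focus channel (DAPI by default),
    builds the focus curve, and returns the Gaussian-fitted best focus with
    the curve (its ``fit`` records convergence).
    """
    zs = plan.coarse_positions(center_um)
    planes = [renderer(stage_xy_um, float(zv), plan.focus_channel) for zv in zs]
    f = np.array([tenengrad(p) for p in planes])
    curve = FocusCurve(zs, f)
    best = fit_best_focus(curve, plan.coarse_step_um)
    return best, curve


def make_scene_renderer(
    scene: GroundTruthScene,
    optics: OpticsModel,
    shape_px: tuple[int, int],
    apply_noise: bool = True,
) -> SceneRenderer:
    """Adapt the simulator to the autofocus renderer interface."""

    def _render(stage_xy_um, z_um, channel):
        return render_plane(scene, optics, stage_xy_um, shape_px, z_um, channel, apply_noise)

    return _render
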