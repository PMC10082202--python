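"""AIF fusion, shading correction, registration, stitching."""

import numpy as np
import pytest

import mfscan as mf
from mfscan import aif_preprocess as pre
from mfscan.autofocus import tenengrad

from conftest import TILE_SHAPE, TILE_STAGE_UM, make_tile_scene


class TestSplitPatches:
    def test_tile_equal_to_patch_is_single_window(self):
        wins = pre.split_patches((600, 600), 600, 50)
        assert wins == [(0, 600, 0, 600)]

    def test_full_fov_cover_and_overlap(self):
        # the camera tile geometry: 4000 x 3700 px, 600-px patches
        shape, size, ov = (3700, 4000), 600, 50
        wins = pre.split_patches(shape, size, ov)
        covered = np.zeros(shape, dtype=bool)
        for y0, y1, x0, x1 in wins:
            covered[y0:y1, x0:x1] = True
        assert covered.all()
        ys = sorted({w[0] for w in wins})
        xs = sorted({w[2] for w in wins})
        for s in (np.diff(ys), np.diff(xs)):
            assert np.all(s <= size - ov)

    def test_zero_overlap_partitions_interior(self):
        wins = pre.split_patches((1200, 1200), 600, 0)
        areas = sum((y1 - y0) * (x1 - x0) for y0, y1, x0, x1 in wins)
        assert areas == 1200 * 1200  # no double coverage
        assert len(wins) == 4

    def test_overlap_must_be_less_than_size(self):
        with pytest.raises(ValueError):
            pre.split_patches((1000, 1000), 100, 100)


class TestFuseAif:
    def test_single_plane_stack_is_identity(self, clean_optics, flat_scene):
        tile = mf.render_tile(flat_scene, clean_optics, (0.0, 0.0), (200, 180),
                              [0.0], apply_noise=False)
        aif = pre.fuse_aif(tile, 128, 16)
        assert np.allclose(aif.data, tile.data[:, 0], atol=1e-9)

    def test_globally_sharp_plane_selected_everywhere(self, clean_optics):
        scene = make_tile_scene(seed=5, amplitude_um=0.0)
        zs = np.array([-15.0, 0.0, 15.0])  # cells all at z = 0
        tile = mf.render_tile(scene, clean_optics, TILE_STAGE_UM, TILE_SHAPE, zs,
                              apply_noise=False)
        aif = pre.fuse_aif(tile, 112, 0)
        ci = tile.channel_index("CK")
        occupied = [
            k for k, (y0, y1, x0, x1) in enumerate(pre.split_patches(TILE_SHAPE, 112, 0))
            if tile.data[ci, 1, y0:y1, x0:x1].max() > 2 * clean_optics.background
        ]
        choices = aif.z_choice_map[ci].ravel()
        assert all(choices[k] == 1 for k in occupied)
        assert np.allclose(aif.data[ci], tile.data[ci, 1], atol=1e-9)

    def test_objects_at_different_depths_both_in_focus(self, clean_optics):
        # two cells 20 um apart axially, in different patches
        surf = mf.generate_surface(120.0, amplitude_um=0.0, seed=0)
        scene = mf.populate_scene(surf, 2, 0, 0, 0, seed=12, min_distance_um=40, margin_um=20)
        o1, o2 = scene.objects
        objs = [
            mf.SceneObject(o1.id, o1.cls, o1.x_um, o1.y_um, -10.0, o1.diameter_um, o1.channel_intensity),
            mf.SceneObject(o2.id, o2.cls, o2.x_um, o2.y_um, +10.0, o2.diameter_um, o2.channel_intensity),
        ]
        scene = mf.GroundTruthScene(tuple(objs), scene.slide_extent_um, scene.surface, scene.seed)
        zs = np.arange(-15.0, 15.1, 5.0)
        tile = mf.render_tile(scene, clean_optics, (0.0, 0.0), (520, 520), zs, apply_noise=False)
        aif = pre.fuse_aif(tile, 260, 0)
        ci = tile.channel_index("CK")
        chosen = set(aif.z_choice_map[ci].ravel().tolist())
        assert {1, 5} <= chosen  # z = -10 and z = +10 both selected somewhere
        # per-patch AIF sharpness dominates every single plane (zero overlap)
        for (y0, y1, x0, x1) in pre.split_patches((520, 520), 260, 0):
            t_aif = tenengrad(aif.data[ci, y0:y1, x0:x1])
            t_best = max(tenengrad(tile.data[ci, z, y0:y1, x0:x1]) for z in range(len(zs)))
            assert t_aif >= t_best - 1e-9


class TestFlatfield:
    def _tiles(self, field, levels):
        return [
            pre.AifTile(np.stack([lv * field] * 3), (0.0, 0.0), mf.CHANNELS)
            for lv in levels
        ]

    @staticmethod
    def _vignette(shape, strength=0.2):
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2, (w - 1) / 2
        return 1.0 - strength * ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)

    def test_constant_tiles_give_unit_field(self):
        field = pre.estimate_flatfield(self._tiles(np.ones((64, 64)), [0.5, 0.5, 0.5]), 8)
        assert np.allclose(field, 1.0, atol=1e-9)

    def test_recovers_synthetic_vignette(self):
        v = self._vignette((96, 96))
        field = pre.estimate_flatfield(self._tiles(v, [0.4, 0.5, 0.6, 0.7]), 4)
        ratio = field[0] / (v / v.mean())
        assert np.abs(ratio - 1.0).max() < 0.05

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(0)
        tiles = self._tiles(0.5 + 0.1 * rng.random((64, 64)), [1.0, 1.1, 0.9])
        field = pre.estimate_flatfield(tiles, 8)
        for ci in range(field.shape[0]):
            assert field[ci].mean() == pytest.approx(1.0, abs=1e-6)

    def test_scale_equivariance(self):
        v = self._vignette((64, 64))
        t1 = self._tiles(v, [0.4, 0.5, 0.6])
        t2 = [pre.AifTile(3.0 * t.data, t.stage_xy_um, t.channel_names) for t in t1]
        assert np.allclose(pre.estimate_flatfield(t1, 8), pre.estimate_flatfield(t2, 8))

    def test_requires_three_tiles(self):
        with pytest.raises(ValueError):
            pre.estimate_flatfield(self._tiles(np.ones((8, 8)), [1.0, 1.0]), 2)

    def test_apply_identity_and_cancellation(self):
        v = self._vignette((64, 64))
        tile = pre.AifTile(np.stack([0.5 * v] * 3), (0.0, 0.0), mf.CHANNELS)
        ones = np.ones_like(tile.data)
        assert np.allclose(pre.apply_flatfield(tile, ones).data, tile.data)
        field = np.stack([v / v.mean()] * 3)
        corrected = pre.apply_flatfield(tile, field)
        assert np.ptp(corrected.data) < 1e-9  # constant after exact correction

    def test_round_trip_field_is_flat(self):
        v = self._vignette((96, 96))
        tiles = self._tiles(v, [0.4, 0.5, 0.6, 0.7])
        field = pre.estimate_flatfield(tiles, 4)
        corrected = [pre.apply_flatfield(t, field) for t in tiles]
        refit = pre.estimate_flatfield(corrected, 4)
        assert np.abs(refit - 1.0).max() < 0.02

    def test_nonpositive_field_rejected(self):
        tile = pre.AifTile(np.ones((3, 8, 8)), (0.0, 0.0), mf.CHANNELS)
        with pytest.raises(ValueError):
            pre.apply_flatfield(tile, np.zeros((3, 8, 8)))


def _render_pair(seed, true_offset_px, shape=(180, 160), channel="DAPI", noise=False):
    """Two overlapping views of one flat scene; tile B truly at ``true_offset_px``."""
    opt = mf.OpticsModel(vignetting_strength=0.0)
    if not noise:
        opt = opt.noiseless()
    surf = mf.generate_surface(60.0, amplitude_um=0.0, seed=seed)
    scene = mf.populate_scene(surf, 10, 0, 0, 0, seed=seed, min_distance_um=5, margin_um=8)
    pix = opt.pixel_size_um

    def at(dy, dx):
        return mf.render_plane(scene, opt, (dx * pix, dy * pix), shape, 0.0, channel,
                               apply_noise=noise)

    return at(0, 0), at(*true_offset_px)


class TestRegisterPair:
    NOMINAL = (0.0, 120.0)

    def test_identical_tiles_give_zero_shift(self):
        a, _ = _render_pair(1, (0, 0))
        s = pre.register_pair(a, a, (0.0, 0.0))
        assert (s.dy, s.dx) == (0.0, 0.0)
        assert s.reliable

    def test_integer_shift_recovered_exactly(self):
        a, b = _render_pair(2, (3.0, 118.0))
        s = pre.register_pair(a, b, self.NOMINAL)
        assert s.reliable
        assert s.dy == pytest.approx(3.0, abs=0.1)
        assert s.dx == pytest.approx(-2.0, abs=0.1)

    def test_fourier_subpixel_shift_recovered(self):
        # pure subpixel translation of the same strip (periodic shift)
        a, _ = _render_pair(3, (0, 0))
        from scipy.ndimage import fourier_shift
        b = np.fft.ifft2(fourier_shift(np.fft.fft2(a), (-0.4, 0.7))).real
        s = pre.register_pair(a, b, (0.0, 0.0), min_overlap_px=32)
        assert s.reliable
        assert s.dy == pytest.approx(0.4, abs=0.1)
        assert s.dx == pytest.approx(-0.7, abs=0.1)

    def test_empty_overlap_flagged_unreliable(self):
        opt = mf.OpticsModel().clean()
        surf = mf.generate_surface(40.0, amplitude_um=0.0, seed=0)
        empty = mf.populate_scene(surf, 0, 0, 0, 0, seed=0)
        a = mf.render_plane(empty, opt, (0.0, 0.0), (180, 160), 0.0, "DAPI", False)
        s = pre.register_pair(a, a.copy(), self.NOMINAL)
        assert not s.reliable
        assert (s.dy, s.dx) == (0.0, 0.0)

    def test_implausibly_large_residual_rejected(self):
        a, b = _render_pair(4, (0.0, 120.0))
        s = pre.register_pair(a, b, (0.0, 80.0), max_residual_px=16.0)
        # true residual would be +40 px in x: beyond the stage bound
        assert not s.reliable

    def test_jittered_pairs_recovered_subquarter_pixel(self):
        rng = np.random.default_rng(0)
        errs = []
        for seed in range(40):
            jy, jx = rng.uniform(-0.5, 0.5, 2)
            a, b = _render_pair(seed, (jy, 120.0 + jx))
            s = pre.register_pair(a, b, self.NOMINAL)
            if s.reliable:
                errs.append(max(abs(s.dy - jy), abs(s.dx - jx)))
        assert len(errs) >= 35
        assert np.median(errs) < 0.25
        assert max(errs) < 1.0


class TestStitch:
    @staticmethod
    def _grid(seed, jitter=0.5, tilt=0.002, shape=(200, 180), ov=40):
        opt = mf.OpticsModel().clean()
        surf = mf.generate_surface((100.0, 100.0), amplitude_um=0.0, seed=seed)
        scene = mf.populate_scene(surf, 8, 3, 0, 0, seed=seed, min_distance_um=14, margin_um=10)
        tiles, true_off = mf.render_wsi_scan(scene, opt, (2, 2), shape, ov, [0.0],
                                             stage_jitter_px=jitter, tilt_rad=tilt,
                                             seed=seed, apply_noise=False)
        aif = [pre.fuse_aif(t, 128, 0) for t in tiles]
        return scene, opt, aif, true_off, shape, ov

    def test_single_tile_mosaic_is_identity(self, clean_optics, flat_scene):
        tile = mf.render_tile(flat_scene, clean_optics, (0.0, 0.0), (100, 90), [0.0],
                              apply_noise=False)
        aif = pre.fuse_aif(tile, 64, 0)
        mosaic = pre.stitch([aif], (1, 1), (100, 90), 20, {})
        assert np.allclose(mosaic.data, aif.data, atol=1e-9)
        assert np.allclose(mosaic.tile_offsets_px, 0.0)

    def test_two_by_two_matches_widefield_oracle(self):
        scene, opt, aif, true_off, shape, ov = self._grid(seed=21)
        shifts = pre.register_grid(aif, (2, 2), shape, ov)
        mosaic = pre.stitch(aif, (2, 2), shape, ov, shifts)
        H, W = mosaic.data.shape[-2:]
        oracle = np.stack([
            mf.render_ideal_plane(scene, opt, (0.0, 0.0), (H, W), ch) for ch in mf.CHANNELS
        ])
        err = np.abs(mosaic.data - oracle)[:, mosaic.coverage].mean()
        assert err < 1e-2

    def test_offsets_match_scan_ground_truth(self):
        scene, opt, aif, true_off, shape, ov = self._grid(seed=22)
        shifts = pre.register_grid(aif, (2, 2), shape, ov)
        mosaic = pre.stitch(aif, (2, 2), shape, ov, shifts)
        est = mosaic.tile_offsets_px.reshape(2, 2, 2)
        # pairs whose strip holds no cells fall back to the nominal offset,
        # which is still within the jitter + tilt bound of the truth
        assert np.abs(est - true_off).max() < 1.0

    def test_loop_closure_below_one_pixel(self):
        scene, opt, aif, true_off, shape, ov = self._grid(seed=23)
        h, w = shape
        # measure all four edges of the 2x2 loop independently
        right0 = pre.register_pair(aif[0], aif[1], (0.0, float(w - ov)))
        down1 = pre.register_pair(aif[1], aif[3], (float(h - ov), 0.0))
        down0 = pre.register_pair(aif[0], aif[2], (float(h - ov), 0.0))
        right2 = pre.register_pair(aif[2], aif[3], (0.0, float(w - ov)))
        assert all(s.reliable for s in (right0, down1, down0, right2))
        path_a = np.array([right0.dy + down1.dy, right0.dx + down1.dx])
        path_b = np.array([down0.dy + right2.dy, down0.dx + right2.dx])
        assert np.abs(path_a - path_b).max() < 1.0

    def test_disconnected_tile_raises(self):
        scene, opt, aif, true_off, shape, ov = self._grid(seed=24)
        with pytest.raises(ValueError, match="not connected"):
            pre.stitch(aif, (2, 2), shape, ov, {})
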