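"""Synthetic tube scenes and the degraded snap renderer."""

import numpy as np
import pytest

from rhizopan.acquisition import AcquisitionPlan
from rhizopan.synthetic import (MULTISPECTRAL_BANDS, CameraModel,
                                ReflectionParams, RootParams, SceneError,
                                TubeScene, acquire, default_camera,
                                generate_scene, render_snap,
                                soil_reference_ceiling)


class TestSceneGeneration:
    def test_deterministic_for_fixed_seed(self):
        a = generate_scene(tube_len_mm=40, seed=5)
        b = generate_scene(tube_len_mm=40, seed=5)
        assert np.array_equal(a.texture, b.texture)
        assert not np.array_equal(
            a.texture, generate_scene(tube_len_mm=40, seed=6).texture)

    def test_no_roots_stays_below_soil_ceiling(self):
        s = generate_scene(tube_len_mm=40, seed=5,
                           root_params=RootParams(n_roots=0))
        assert s.texture.max() <= soil_reference_ceiling(s)

    def test_root_cover_grows_with_population(self):
        fracs = []
        for n in (0, 2, 4, 8):
            s = generate_scene(tube_len_mm=40, seed=5,
                               root_params=RootParams(n_roots=n))
            thresh = soil_reference_ceiling(s)
            fracs.append((s.texture.max(axis=-1) > thresh).mean())
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]

    def test_angular_seam_is_continuous(self):
        s = generate_scene(tube_len_mm=40, seed=5)
        # wrap-generated soil: the seam gradient matches interior gradients
        seam = np.abs(s.texture[:, 0] - s.texture[:, -1]).mean()
        interior = np.abs(np.diff(s.texture, axis=1)).mean()
        assert seam < 3 * interior

    def test_scale_ties_width_to_circumference(self):
        s = generate_scene(tube_id_mm=63.5, tube_len_mm=40, seed=0)
        assert s.width_px * s.mm_per_px == pytest.approx(np.pi * 63.5,
                                                         abs=s.mm_per_px)

    def test_zero_size_scene_rejected(self):
        with pytest.raises(SceneError):
            generate_scene(tube_len_mm=0, seed=0)
        with pytest.raises(SceneError):
            generate_scene(width_px=0, seed=0)


class TestRenderSnap:
    def test_identity_degradation_reproduces_scene_columns(self):
        # a texture constant along the tube axis makes the vertical
        # interpolation exact, so the render must equal the scene columns
        base = generate_scene(tube_len_mm=40, seed=2)
        tex = np.tile(base.texture[10:11], (base.height_px, 1, 1))
        scene = TubeScene(texture=tex, mm_per_px=base.mm_per_px,
                          tube_id_mm=base.tube_id_mm, tube_len_mm=40,
                          seed=2, root_params=base.root_params)
        cam = CameraModel()
        snap = render_snap(scene, cam, angle_deg=36.0, depth_mm=20.0)
        cols = (np.arange(cam.sensor_w_px) + int(round(36 * 2 - 60))) \
            % scene.width_px
        expected = tex[0][cols]
        assert np.abs(snap.pixels - expected[None, :, :]).max() <= 1 / 255

    def test_window_mean_matches_source_mean(self, scene75, camera_clean):
        snap = render_snap(scene75, camera_clean, 72.0, 30.0)
        x0 = int(round(72 * scene75.px_per_deg)) - 60
        cols = (np.arange(120) + x0) % scene75.width_px
        rows = slice(int((30 - 14) / scene75.mm_per_px),
                     int((30 + 14) / scene75.mm_per_px))
        window = scene75.texture[rows][:, cols]
        assert snap.pixels.mean() == pytest.approx(window.mean(), rel=0.01)

    def test_streaks_touch_only_their_region(self, scene75, plan75):
        cam0 = default_camera(scene75, plan75)
        cam1 = default_camera(scene75, plan75,
                              reflection=ReflectionParams(n_streaks=2))
        a = render_snap(scene75, cam0, 36.0, 15.0,
                        rng=np.random.default_rng(5))
        b = render_snap(scene75, cam1, 36.0, 15.0,
                        rng=np.random.default_rng(5))
        diff = np.abs(a.pixels - b.pixels).max(axis=-1)
        assert b.streak_mask.any()
        assert diff[b.streak_mask].mean() > 0.1
        from scipy.ndimage import binary_dilation
        far = ~binary_dilation(b.streak_mask, iterations=4)
        assert diff[far].max() <= 2e-3

    def test_seam_crossing_render_matches_rolled_scene(self, scene75):
        cam = CameraModel()
        half = scene75.width_px // 2
        rolled = TubeScene(texture=np.roll(scene75.texture, half, axis=1),
                           mm_per_px=scene75.mm_per_px,
                           tube_id_mm=scene75.tube_id_mm,
                           tube_len_mm=scene75.tube_len_mm, seed=0,
                           root_params=scene75.root_params)
        a = render_snap(scene75, cam, 350.0, 30.0)
        b = render_snap(rolled, cam, (350.0 + 180.0) % 360, 30.0)
        assert np.abs(a.pixels - b.pixels).max() <= 1e-6

    def test_depth_outside_tube_rejected(self, scene75, camera_clean):
        with pytest.raises(SceneError):
            render_snap(scene75, camera_clean, 0.0, scene75.tube_len_mm + 1)

    def test_multispectral_band_gain_scales_intensity(self, scene75):
        scene = TubeScene(texture=scene75.texture,
                          mm_per_px=scene75.mm_per_px,
                          tube_id_mm=scene75.tube_id_mm,
                          tube_len_mm=scene75.tube_len_mm, seed=0,
                          root_params=scene75.root_params,
                          band_gains={850: 1.5, 395: 0.5})
        cam = CameraModel()
        hi = render_snap(scene, cam, 0.0, 30.0, band_nm=850)
        lo = render_snap(scene, cam, 0.0, 30.0, band_nm=395)
        assert hi.pixels.ndim == 2
        assert hi.pixels.mean() > 2.5 * lo.pixels.mean()


class TestAcquire:
    def test_counts_and_manifest_layout(self, scene75, plan75, camera_clean,
                                         snaps_clean):
        snaps, records = snaps_clean
        assert len(snaps) == plan75.n_strips * plan75.snaps_per_rotation == 50
        angles = {r["angle_deg"] for r in records}
        assert angles == {i * 36.0 for i in range(10)}
        depths = {r["depth_mm"] for r in records}
        assert depths == {0.0, 15.0, 30.0, 45.0, 60.0}
        keys = {(r["strip_idx"], r["angle_idx"]) for r in records}
        assert len(keys) == len(records)

    def test_reproducible_across_runs(self, scene75, plan75, camera_streaks):
        cam = CameraModel(
            reflection=ReflectionParams(n_streaks=2),
            exposure_jitter_sd=0.05, noise_sd=2 / 255)
        s1, _ = acquire(scene75, plan75, cam, seed=9)
        s2, _ = acquire(scene75, plan75, cam, seed=9)
        assert all(np.array_equal(a.pixels, b.pixels)
                   for a, b in zip(s1, s2))

    def test_multispectral_mode_multiplies_snaps(self, scene75, camera_clean):
        plan1 = AcquisitionPlan(tube_len_mm=15.0)
        snaps, records = acquire(scene75, plan1, camera_clean, seed=0,
                                 bands=list(MULTISPECTRAL_BANDS))
        assert len(snaps) == 10 * len(MULTISPECTRAL_BANDS)
        assert {r["band_nm"] for r in records} == set(MULTISPECTRAL_BANDS)
        assert all(s.pixels.ndim == 2 for s in snaps)

    def test_zero_overlap_windows_tile_the_circle(self, scene75):
        plan = AcquisitionPlan(angular_overlap_frac=0.0, tube_len_mm=15.0)
        assert plan.snaps_per_rotation == 6
        cover = np.zeros(360)
        for i in range(6):
            a0 = i * 60.0 - 30.0
            idx = (np.arange(a0, a0 + 60) % 360).astype(int)
            cover[idx] += 1
        assert np.all(cover == 1)

    def test_angular_coverage_geometry(self, plan75):
        # 60° windows advanced 36°: everything covered, and exactly the
        # overlap bands (2/3 of the circumference) are covered twice
        cover = np.zeros(360)
        for i in range(plan75.snaps_per_rotation):
            a0 = i * 36.0 - 30.0
            idx = (np.arange(a0, a0 + 60) % 360).astype(int)
            cover[idx] += 1
        assert cover.min() >= 1
        assert (cover >= 2).mean() == pytest.approx(2 / 3, abs=0.02)
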