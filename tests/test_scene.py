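"""Synthetic scene generator: projection oracle, rendering, flights, crops."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from avistereo import stereo
from avistereo.scene import (
    SILHOUETTE_SIZES,
    OutOfViewError,
    SceneConfig,
    WorldBird,
    default_assembly,
    generate_crop_dataset,
    generate_silhouette_campaign,
    project_bird,
    rasterized_observation,
    render_stereo_frames,
    simulate_flight,
)

RIG = stereo.StereoRig()
ASM = default_assembly()


class TestProjectBird:
    @given(d=st.floats(60.0, 350.0), h=st.floats(40.0, 220.0))
    def test_disparity_matches_expected_disparity(self, d, h):
        bird = WorldBird(distance=d, height=h)
        try:
            pu = project_bird(bird, "upper", RIG, ASM)
            pl = project_bird(bird, "lower", RIG, ASM)
        except OutOfViewError:
            return
        cont, _ = stereo.expected_disparity(pu.d_b, RIG)
        assert pu.y - pl.y == pytest.approx(cont, rel=1e-9)

    def test_wingspan_at_300m(self):
        bird = WorldBird(distance=250.0, height=160.0, wingspan=1.5)
        proj = project_bird(bird, "upper", RIG, ASM)
        expected = 1.5 * 2673.9 / proj.d_b
        assert proj.p_w == pytest.approx(expected, rel=1e-3)

    def test_doubling_distance_halves_extent(self):
        near = project_bird(WorldBird(distance=100.0, height=64.0), "upper", RIG, ASM)
        far = project_bird(
            WorldBird(distance=200.0, height=128.0), "upper", RIG, ASM
        )
        assert far.p_w == pytest.approx(near.p_w / 2.0, rel=0.02)

    def test_azimuth_outside_fov_raises(self):
        bird = WorldBird(distance=150.0, height=100.0, azimuth_deg=40.0)
        with pytest.raises(OutOfViewError):
            project_bird(bird, "upper", RIG, ASM)

    def test_localize_round_trip_inverse(self):
        bird = WorldBird(distance=150.0, height=100.0)
        pu = project_bird(bird, "upper", RIG, ASM)
        pl = project_bird(bird, "lower", RIG, ASM)
        loc = stereo.localize(stereo.StereoObservation(pu.y, pl.y), RIG)
        assert loc.d == pytest.approx(150.0, rel=1e-9)
        assert loc.h == pytest.approx(100.0, rel=1e-9)


class TestRenderStereoFrames:
    def small_cfg(self, **kw):
        # down-scaled rig keeps render tests quick
        rig = stereo.StereoRig(vsr_axis=400)
        from avistereo.optics import LensSpec, OpticalAssembly, SensorSpec

        sensor = SensorSpec("mini", 400, 300, 3.680, 2.760)
        return SceneConfig(rig=rig, assembly=OpticalAssembly(sensor, LensSpec(3.0)), **kw)

    def test_empty_scene_is_background_only(self):
        cfg = self.small_cfg(noise_sigma=0.0)
        up, lo = render_stereo_frames([], cfg)
        assert (up.pixels == cfg.sky_level).all()
        assert (lo.pixels == cfg.sky_level).all()

    def test_single_bird_renders_one_dark_silhouette(self):
        cfg = self.small_cfg(noise_sigma=0.0)
        bird = WorldBird(distance=40.0, height=26.0, wingspan=1.5)
        up, _ = render_stereo_frames([bird], cfg)
        proj = project_bird(bird, "upper", cfg.rig, cfg.assembly)
        dark = up.pixels < 128
        rr, cc = np.nonzero(dark)
        assert dark.any()
        assert abs(cc.mean() - (proj.x - 1)) <= 1.0
        # the triangle's mass centre sits a sixth of its height below the
        # bounding-box centre (centroid of a triangle)
        assert abs(rr.mean() - (proj.y - 1 + proj.p_h / 6)) <= 1.0

    def test_seeded_rendering_is_bit_identical(self):
        cfg = self.small_cfg(seed=9)
        bird = WorldBird(distance=40.0, height=26.0)
        a = render_stereo_frames([bird], cfg, t=1.0)
        b = render_stereo_frames([bird], cfg, t=1.0)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)


class TestRasterizedObservation:
    def test_matches_continuous_rows_to_subpixel(self):
        bird = WorldBird(distance=150.0, height=100.0)
        pu = project_bird(bird, "upper", RIG, ASM)
        pl = project_bird(bird, "lower", RIG, ASM)
        yu, yd = rasterized_observation(bird, RIG, ASM)
        # binary-mask centroid lands near the triangle centroid, a sixth
        # of the silhouette height below the box centre
        assert abs(yu - (pu.y + pu.p_h / 6)) <= 0.6
        assert abs(yd - (pl.y + pl.p_h / 6)) <= 0.6
        assert abs((yu - yd) - (pu.y - pl.y)) <= 0.5


class TestSimulateFlight:
    def test_circular_orbit_statistics(self):
        birds = simulate_flight(duration=40.0, fps=2.0, seed=5)
        assert len(birds) == 80
        d = np.array([b.distance for b in birds])
        h = np.array([b.height for b in birds])
        assert d.mean() == pytest.approx(143.3, abs=1.0)
        assert h.mean() == pytest.approx(102.9, abs=0.6)
        assert d.std() == pytest.approx(2.5, abs=1.0)

    def test_arc_length_matches_speed(self):
        birds = simulate_flight(duration=10.0, fps=10.0, seed=0,
                                radius_jitter=0.0, height_jitter=0.0)
        az = np.unwrap(np.radians([b.azimuth_deg for b in birds]))
        arc = abs(az[-1] - az[0]) * 143.3
        expected = 15.0 * (len(birds) - 1) / 10.0
        assert arc == pytest.approx(expected, rel=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_flight(duration=0.0)
        with pytest.raises(ValueError):
            simulate_flight(path="zigzag")


class TestCropDataset:
    def test_counts_and_balance(self):
        X, y = generate_crop_dataset(40, 40, seed=1)
        assert X.shape == (80, 100, 100, 3)
        assert X.dtype == np.uint8
        assert (y == 1).sum() == 40 and (y == 0).sum() == 40

    def test_seed_determinism(self):
        a = generate_crop_dataset(25, 25, seed=7)
        b = generate_crop_dataset(25, 25, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_classes_separable_by_dark_area_baseline(self):
        """A trivial dark-pixel-count threshold reaches 80%: the floor a
        learned classifier must comfortably beat."""
        X, y = generate_crop_dataset(150, 150, seed=3)
        area = (X[..., 0] < 120).reshape(len(X), -1).sum(axis=1)
        best = 0.0
        for thr in np.unique(area):
            acc = max(
                ((area >= thr) == (y == 1)).mean(),
                ((area < thr) == (y == 1)).mean(),
            )
            best = max(best, acc)
        assert best >= 0.80


class TestSilhouetteCampaign:
    def test_campaign_has_18_scenes(self, campaign):
        assert len(campaign) == 18
        labels = {(s.label, s.db_ref) for s in campaign}
        assert len(labels) == 18

    def test_truth_sidecar_fields(self, campaign):
        for s in campaign:
            assert set(s.truth) >= {
                "label", "db_ref", "distance", "height", "wingspan",
                "p_w_px", "detectable",
            }

    def test_small_target_below_12px_beyond_range(self, campaign):
        for s in campaign:
            if s.label == "small" and s.db_ref >= 200.0:
                assert s.truth["p_w_px"] < 12
                assert not s.truth["detectable"]

    def test_png_sidecar_export(self, tmp_path, rig, assembly):
        scenes = generate_silhouette_campaign(
            rig, assembly, distances=(100.0,), sizes={"large": (1.5, 0.5)},
            out_dir=tmp_path,
        )
        assert len(scenes) == 1
        assert len(list(tmp_path.glob("*.png"))) == 4
        assert len(list(tmp_path.glob("*_truth.json"))) == 1
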