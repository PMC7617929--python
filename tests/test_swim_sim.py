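"""Generator-level checks: physics limits, counting laws, determinism and
the ground-truth bookkeeping every downstream recovery test relies on."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from rhizotrack import swim_sim as ss
from rhizotrack.halo import four_pl


class TestSimulateTracks:
    def test_ballistic_limit_exact_steps(self, imaging512):
        """No tumbling, no rotational diffusion: straight lines with
        per-step displacement speed/fps to rounding error."""
        sp = ss.SwimmerParams(n_cells=5, mean_speed=44.0, speed_sd=0.0,
                              tumble_rate=0.0, rot_diffusion=0.0,
                              duration=2.0, fov_width=5000, fov_height=5000,
                              seed=1)
        truth = ss.simulate_tracks(sp, imaging512)
        for c in truth:
            steps = np.hypot(np.diff(c.x_um), np.diff(c.y_um))
            assert np.allclose(steps, 44.0 / imaging512.fps, rtol=1e-9)
            end_to_end = np.hypot(c.x_um[-1] - c.x_um[0], c.y_um[-1] - c.y_um[0])
            assert end_to_end == pytest.approx(
                44.0 * (c.n_points - 1) / imaging512.fps, rel=1e-9)

    def test_three_frame_record(self, imaging512):
        sp = ss.SwimmerParams(n_cells=1, duration=0.3, fov_width=5000,
                              fov_height=5000, seed=2)
        truth = ss.simulate_tracks(sp, imaging512)
        assert truth.cells[0].n_points == 3

    def test_fov_exit_truncates_record(self, imaging512):
        # tiny FOV: every fast cell leaves well before the 30 s duration
        sp = ss.SwimmerParams(n_cells=50, mean_speed=44.0, duration=30.0,
                              fov_width=20.0, fov_height=20.0, seed=3)
        truth = ss.simulate_tracks(sp, imaging512)
        for c in truth:
            assert c.n_points < 300
            assert np.all((c.x_um >= 0) & (c.x_um <= 20.0))
            assert np.all((c.y_um >= 0) & (c.y_um <= 20.0))
            assert np.all(np.diff(c.frames) == 1)

    def test_population_moments_match_generative_values(self, imaging512):
        """Wildtype glucose parameters: sampled speeds and the realised
        tumble count land within sampling error of the generative values."""
        sp = ss.SwimmerParams(n_cells=600, mean_speed=44.0, speed_sd=7.0,
                              tumble_rate=0.11, duration=30.0,
                              fov_width=5000.0, fov_height=5000.0, seed=4)
        truth = ss.simulate_tracks(sp, imaging512)
        speeds = np.array([c.speed for c in truth])
        assert abs(speeds.mean() - 44.0) < 2 * 7.0 / np.sqrt(len(speeds))
        total_t = truth.total_time(imaging512.fps)
        n_ev = truth.total_tumbles()
        se = np.sqrt(max(n_ev, 1)) / total_t
        assert abs(n_ev / total_t - 0.11) < 3 * se

    def test_determinism(self, imaging512):
        sp = ss.SwimmerParams(n_cells=20, seed=5)
        a = ss.simulate_tracks(sp, imaging512)
        b = ss.simulate_tracks(sp, imaging512)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.x_um, cb.x_um)
            assert np.array_equal(ca.y_um, cb.y_um)
            assert np.array_equal(ca.tumble_frames, cb.tumble_frames)

    @pytest.mark.parametrize("field,value", [
        ("mean_speed", -1.0), ("mean_speed", float("nan")),
        ("tumble_rate", -0.1), ("speed_sd", -1.0), ("duration", 0.0),
        ("n_cells", 0), ("rot_diffusion", float("inf")),
    ])
    def test_invalid_params_name_the_field(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            ss.SwimmerParams(**{field: value})


class TestRenderVideo:
    def test_static_noiseless_centroid(self, imaging512_noiseless):
        from tests.conftest import make_trackset

        truth = make_trackset([[(51.27, 33.81)]], imaging512_noiseless)
        frame = ss.render_frames(truth, imaging512_noiseless)[0].astype(float)
        sig = frame - imaging512_noiseless.background_level
        yy, xx = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
        cx = (sig * xx).sum() / sig.sum()
        cy = (sig * yy).sum() / sig.sum()
        px = imaging512_noiseless.pixel_size
        assert cx == pytest.approx(51.27 / px - 0.5, abs=0.05)
        assert cy == pytest.approx(33.81 / px - 0.5, abs=0.05)

    def test_two_cells_two_maxima(self, imaging512_noiseless):
        from scipy.ndimage import maximum_filter

        from tests.conftest import make_trackset

        truth = make_trackset([[(40.0, 40.0)], [(46.0, 40.0)]],  # 30 px apart
                              imaging512_noiseless)
        frame = ss.render_frames(truth, imaging512_noiseless)[0].astype(float)
        peaks = (frame == maximum_filter(frame, 5)) & \
                (frame > imaging512_noiseless.background_level + 100)
        from scipy.ndimage import label as cc_label
        n_maxima = cc_label(peaks)[1]  # quantisation can tie adjacent pixels
        assert n_maxima == 2

    def test_stack_roundtrip_bit_exact(self, tmp_path, imaging512):
        sp = imaging512.matched_fov(ss.SwimmerParams(n_cells=40, duration=4.0,
                                                     seed=6))
        truth = ss.simulate_tracks(sp, imaging512)
        frames = ss.render_frames(truth, imaging512)
        path = ss.write_stack(frames, tmp_path / "stack.tif", imaging512)
        back, meta = ss.read_stack(path)
        assert np.array_equal(back, frames)
        assert meta["fps"] == imaging512.fps
        assert meta["pixel_size_um"] == imaging512.pixel_size

    def test_frames_beyond_duration_rejected(self, imaging512):
        sp = imaging512.matched_fov(ss.SwimmerParams(n_cells=5, duration=2.0,
                                                     seed=7))
        truth = ss.simulate_tracks(sp, imaging512)
        with pytest.raises(ValueError, match="beyond"):
            ss.render_frames(truth, imaging512, n_frames=3)


class TestHaloTable:
    def test_noiseless_matches_curve_and_row_count(self):
        curves = {("wt", "succinate"): ss.HaloCurve(2.0, 10.0, 40.0, 8.0)}
        tab = ss.generate_halo_table(curves, noise_sd=0.0, replicates=3, seed=0)
        assert len(tab) == 18  # 3 replicates x 6 default concentrations
        expected = four_pl(tab["conc_mM"], 2.0, 10.0, 40.0, 8.0)
        assert np.allclose(tab["diameter_mm"], expected)

    def test_flat_curve_degenerate(self):
        curves = {("ctrl", "glucose"): ss.HaloCurve(1.0, 6.0, 6.0, 8.0)}
        tab = ss.generate_halo_table(curves, noise_sd=0.0, seed=0)
        assert np.allclose(tab["diameter_mm"], 6.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            ss.generate_halo_table(noise_sd=-1.0)


class TestCytometryEvents:
    def test_row_count_is_5000(self):
        events, truth = ss.generate_cytometry_events(1500, 3500, seed=0)
        assert len(events) == 5000
        assert len(truth) == 5000

    def test_all_bacteria_when_no_bacteroids(self):
        _, truth = ss.generate_cytometry_events(100, 0, seed=0)
        assert set(truth["true_label"]) == {"bacteria"}

    def test_ordering_precondition_enforced(self):
        with pytest.raises(ValueError, match="larger"):
            ss.generate_cytometry_events(10, 10, bacteria_mean=(500, 500),
                                         bacteroid_mean=(400, 600))

    def test_determinism(self):
        a, ta = ss.generate_cytometry_events(200, 300, seed=42)
        b, tb = ss.generate_cytometry_events(200, 300, seed=42)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)


class TestNoduleImage:
    def test_zero_nodules_blank(self):
        img = ss.generate_nodule_image(0, seed=0)
        assert img.n_nodules == 0
        assert img.centers.shape == (0, 2)

    def test_truth_count_and_spacing(self):
        img = ss.generate_nodule_image(25, radius_range=(8, 14),
                                       canvas=(900, 1200), seed=1)
        assert img.n_nodules == 25
        d = np.hypot(img.centers[:, None, 0] - img.centers[None, :, 0],
                     img.centers[:, None, 1] - img.centers[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * 14  # non-merging placement

    def test_same_seed_identical_images(self):
        a = ss.generate_nodule_image(10, seed=7)
        b = ss.generate_nodule_image(10, seed=7)
        assert np.array_equal(a.image, b.image)

    def test_impossible_placement_names_constraint(self):
        with pytest.raises(ValueError, match="non-merging"):
            ss.generate_nodule_image(50, radius_range=(10, 14),
                                     canvas=(80, 80), seed=0)

    def test_unknown_stain_rejected(self):
        with pytest.raises(ValueError, match="stain"):
            ss.generate_nodule_image(3, stain="crimson", seed=0)
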