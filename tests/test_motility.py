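"""Track metrics: speed arithmetic, tumble-event segmentation, geometric
invariances, estimator bias bounds on clean trajectories, and population
summaries."""

import numpy as np
import pandas as pd
import pytest

from rhizotrack import swim_sim as ss
from rhizotrack.link import Track
from rhizotrack.motility import (TumbleParams, compute_speed, detect_tumbles,
                                 metrics_table, summarize_population,
                                 track_metrics)

PX, FPS = 0.2, 10.0


def straight_track(speed_um_s, n=40, heading=0.3):
    step = speed_um_s / FPS / PX
    t = np.arange(n)
    return Track(0, t, 100 + t * step * np.cos(heading),
                 100 + t * step * np.sin(heading))


def truth_to_track(cell, pixel_size):
    return Track(cell.cell_id, cell.frames, cell.x_um / pixel_size,
                 cell.y_um / pixel_size)


class TestComputeSpeed:
    def test_ballistic_speed_exact(self):
        mean, _, _ = compute_speed(straight_track(44.0), PX, FPS)
        assert mean == pytest.approx(44.0, rel=1e-6)

    def test_static_track_zero(self):
        tr = Track(0, np.arange(10), np.full(10, 5.0), np.full(10, 7.0))
        assert compute_speed(tr, PX, FPS)[0] == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            compute_speed(Track(0, np.array([0]), np.array([1.0]),
                                np.array([1.0])), PX, FPS)

    def test_gap_steps_flagged_but_counted(self):
        tr = straight_track(40.0, n=12)
        tr.is_gap[6] = True
        mean, speeds, gap_step = compute_speed(tr, PX, FPS)
        assert mean == pytest.approx(40.0, rel=1e-9)
        assert gap_step.sum() == 2  # the step into and out of the gap point


class TestDetectTumbles:
    def test_straight_track_no_events(self):
        assert detect_tumbles(straight_track(44.0), TumbleParams(), PX, FPS).size == 0

    def test_single_right_angle_turn(self):
        """20 straight frames, one instantaneous 90-degree turn, 20 straight
        frames: exactly one event at the turn frame."""
        step = 22.0
        x = np.concatenate([np.arange(21.0) * step, np.full(20, 20 * step)])
        y = np.concatenate([np.zeros(21), np.arange(1, 21.0) * step])
        tr = Track(0, np.arange(41), x, y)
        ev = detect_tumbles(tr, TumbleParams(turn_threshold=50.0), PX, FPS)
        assert list(ev) == [20]

    def test_gap_intervals_never_seed_events(self):
        step = 22.0
        x = np.concatenate([np.arange(21.0) * step, np.full(20, 20 * step)])
        y = np.concatenate([np.zeros(21), np.arange(1, 21.0) * step])
        tr = Track(0, np.arange(41), x, y)
        tr.is_gap[20] = True
        assert detect_tumbles(tr, TumbleParams(), PX, FPS).size == 0

    def test_nearby_flags_merge_to_one_event(self):
        # two moderate kinks 2 frames apart merge under min_run_frames=3
        h = np.zeros(30)
        h[10:] += np.deg2rad(40.0)
        h[12:] += np.deg2rad(40.0)
        x = np.concatenate([[0], np.cumsum(np.cos(h))]) * 22
        y = np.concatenate([[0], np.cumsum(np.sin(h))]) * 22
        tr = Track(0, np.arange(31), x, y)
        ev = detect_tumbles(tr, TumbleParams(turn_threshold=30.0,
                                             min_run_frames=3), PX, FPS)
        assert ev.size == 1

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(5)
        h = np.cumsum(rng.normal(0, 0.3, 60))
        x = np.concatenate([[0], np.cumsum(np.cos(h))]) * 20
        y = np.concatenate([[0], np.cumsum(np.sin(h))]) * 20
        tr = Track(0, np.arange(61), x, y)
        m0 = track_metrics(tr, PX, FPS)
        th = 1.1
        xr = 500 + x * np.cos(th) - y * np.sin(th)
        yr = -200 + x * np.sin(th) + y * np.cos(th)
        m1 = track_metrics(Track(0, np.arange(61), xr, yr), PX, FPS)
        assert m1.mean_speed == pytest.approx(m0.mean_speed, rel=1e-9)
        assert m1.n_tumbles == m0.n_tumbles
        assert m1.tumble_rate == pytest.approx(m0.tumble_rate, rel=1e-9)


class TestRecoveryOnCleanTracks:
    """Estimator checks on simulator truth (no imaging), where the only
    losses are the detector's own: sub-threshold reorientations and event
    merging."""

    @pytest.mark.parametrize("rate", [0.05, 0.1, 0.2])
    def test_tumble_rate_bias_bound(self, rate):
        """|estimate - truth| / truth < 0.25 with >= 10,000 track-seconds."""
        ip = ss.ImagingParams()
        sp = ss.SwimmerParams(n_cells=400, duration=30.0, tumble_rate=rate,
                              fov_width=5000, fov_height=5000, seed=17)
        truth = ss.simulate_tracks(sp, ip)
        assert truth.total_time(ip.fps) >= 10_000
        rates = [track_metrics(truth_to_track(c, ip.pixel_size), ip.pixel_size,
                               ip.fps).tumble_rate for c in truth
                 if c.n_points >= 10]
        est = float(np.nanmean(rates))
        assert abs(est - rate) / rate < 0.25

    def test_population_speed_recovery_pyruvate_params(self, imaging512):
        """Per-cell constant speeds drawn at the pyruvate condition: the
        population mean of per-track mean speeds recovers the generative
        mean within 5%."""
        sp = imaging512.matched_fov(
            ss.SwimmerParams(n_cells=500, mean_speed=38.0, speed_sd=6.0,
                             duration=30.0, seed=18))
        truth = ss.simulate_tracks(sp, imaging512)
        ms = [compute_speed(truth_to_track(c, imaging512.pixel_size),
                            imaging512.pixel_size, imaging512.fps)[0]
              for c in truth if c.n_points >= 10]
        assert abs(np.mean(ms) - 38.0) / 38.0 < 0.05

    def test_zero_inflation_on_short_tracks(self, imaging512):
        """FOV-truncated tracks at 0.11 /s hold mostly zero events, so the
        across-track SD exceeds the mean (the Table-style 0.11 +- 0.23
        pattern)."""
        sp = imaging512.matched_fov(
            ss.SwimmerParams(n_cells=400, duration=30.0, tumble_rate=0.11,
                             seed=19))
        truth = ss.simulate_tracks(sp, imaging512)
        tracks = [truth_to_track(c, imaging512.pixel_size) for c in truth
                  if c.n_points >= 10]
        m = metrics_table(tracks, imaging512.pixel_size, imaging512.fps)
        rates = m.tumble_rate_per_s.dropna()
        assert 0.11 * m[m.tumble_rate_per_s.notna()].duration_s.mean() < 1
        assert rates.std() > rates.mean()

    def test_framerate_consistency(self):
        """Downsampling a 20 fps simulation to 10 fps changes the recovered
        mean speed by < 5%."""
        ip20 = ss.ImagingParams(fps=20.0)
        sp = ss.SwimmerParams(n_cells=150, duration=15.0, fov_width=5000,
                              fov_height=5000, seed=20)
        truth = ss.simulate_tracks(sp, ip20)
        full, half = [], []
        for c in truth:
            tr = truth_to_track(c, ip20.pixel_size)
            full.append(compute_speed(tr, ip20.pixel_size, 20.0)[0])
            sub = Track(c.cell_id, np.arange((c.n_points + 1) // 2),
                        tr.x[::2], tr.y[::2])
            if sub.n_points >= 2:
                half.append(compute_speed(sub, ip20.pixel_size, 10.0)[0])
        assert abs(np.mean(half) - np.mean(full)) / np.mean(full) < 0.05


class TestSummaries:
    def _metrics_df(self, speeds, group="g1"):
        tracks = [straight_track(s, n=30) for s in speeds]
        for i, tr in enumerate(tracks):
            tr.track_id = i
        return metrics_table(tracks, PX, FPS, group=group)

    def test_mean_and_sd_arithmetic(self):
        out = summarize_population(self._metrics_df([40.0, 44.0, 48.0]))
        assert out.n_tracks.iloc[0] == 3
        assert out.speed_mean.iloc[0] == pytest.approx(44.0, rel=1e-9)
        assert out.speed_sd.iloc[0] == pytest.approx(4.0, rel=1e-6)

    def test_identical_groups_identical_rows(self):
        df = pd.concat([self._metrics_df([40, 44, 48], "a"),
                        self._metrics_df([40, 44, 48], "b")])
        out = summarize_population(df)
        a = out[out.group == "a"].drop(columns="group").reset_index(drop=True)
        b = out[out.group == "b"].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_group_warns_with_zero_row(self):
        df = self._metrics_df([40.0])
        df.loc[:, "flags"] = "too-short"
        with pytest.warns(UserWarning, match="no usable tracks"):
            out = summarize_population(df)
        assert out.n_tracks.iloc[0] == 0
        assert np.isnan(out.speed_mean.iloc[0])

    def test_che1_like_ordering_recovered(self, imaging512):
        """A faster, less tumbly mutant-like population keeps its generative
        ordering after metrics: higher speed, lower tumble rate than
        wildtype-like."""
        groups = {"wildtype": (44.0, 0.11, 41), "che1-like": (54.0, 0.08, 43)}
        frames_ = []
        for name, (spd, rate, seed) in groups.items():
            sp = imaging512.matched_fov(
                ss.SwimmerParams(n_cells=500, mean_speed=spd, tumble_rate=rate,
                                 duration=30.0, seed=seed))
            truth = ss.simulate_tracks(sp, imaging512)
            tracks = [truth_to_track(c, imaging512.pixel_size) for c in truth
                      if c.n_points >= 10]
            frames_.append(metrics_table(tracks, imaging512.pixel_size,
                                         imaging512.fps, group=name))
        out = summarize_population(pd.concat(frames_, ignore_index=True))
        out = out.set_index("group")
        assert out.loc["che1-like", "speed_mean"] > out.loc["wildtype", "speed_mean"]
        assert out.loc["che1-like", "tumble_mean"] < out.loc["wildtype", "tumble_mean"]
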