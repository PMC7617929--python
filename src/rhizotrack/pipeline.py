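"""End-to-end capillary-assay pipeline: simulate → render → detect → link →
per-track metrics, over as many replicate recordings as needed.

A single 512 x 512 px field of view at 0.2 μm/px covers only ~100 μm, so a
cell swimming at ~40 μm/s stays in view for about a second; population-level
tumble statistics therefore need many replicate videos, exactly as the
original assay pooled replicate capillary recordings.  ``run_capillary_assay``
keeps simulating fresh seeded videos until the requested number of swimmers
and accumulated track-seconds are reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .detect import DetectionParams, default_detection_params, detect_stack
from .link import LinkParams, default_link_params, filter_tracks, link_detections
from .motility import TumbleParams, metrics_table
from .swim_sim import GroundTruthTrackSet, ImagingParams, SwimmerParams, \
    render_frames, simulate_tracks

__all__ = ["CapillaryResult", "run_capillary_assay", "process_stack"]

log = logging.getLogger(__name__)


@dataclass
class CapillaryResult:
    metrics: pd.DataFrame        # per-track metrics across all videos
    n_swimmers: int              # ground-truth cells simulated
    track_seconds: float         # summed duration of measured tracks
    n_videos: int

    @property
    def mean_speed(self) -> float:
        return float(self.metrics["mean_speed_um_s"].mean())

    @property
    def mean_tumble_rate(self) -> float:
        ok = self.metrics[~self.metrics["flags"].str.contains("too-short")]
        return float(ok["tumble_rate_per_s"].mean())


def process_stack(frames: np.ndarray, imaging: ImagingParams,
                  detection: DetectionParams, link_params: LinkParams,
                  tumble: TumbleParams, group: str | None = None) -> pd.DataFrame:
    """detect → link → filter → metrics for one rendered stack."""
    dets = detect_stack(frames, detection)
    tracks = filter_tracks(link_detections(dets, link_params), link_params)
    return metrics_table(tracks, imaging.pixel_size, imaging.fps, tumble,
                         group=group)


def run_capillary_assay(swimmer: SwimmerParams, imaging: ImagingParams, *,
                        min_swimmers: int = 500,
                        min_track_seconds: float = 0.0,
                        max_videos: int = 400,
                        detection: DetectionParams | None = None,
                        link_params: LinkParams | None = None,
                        tumble: TumbleParams | None = None,
                        group: str | None = None,
                        seed: int = 0) -> CapillaryResult:
    """Replicate-video pipeline with the swimmer FOV matched to the camera.

    Video seeds are spawned deterministically from ``seed``; detection and
    linking parameters default to values derived from the configuration.
    """
    detection = detection or default_detection_params(imaging)
    link_params = link_params or default_link_params(swimmer, imaging)
    tumble = tumble or TumbleParams()
    swimmer = imaging.matched_fov(swimmer)

    ss = np.random.SeedSequence(seed)
    chunks: list[pd.DataFrame] = []
    n_swimmers = 0
    track_seconds = 0.0
    n_videos = 0
    for child in ss.spawn(max_videos):
        if n_videos > 0 and n_swimmers >= min_swimmers \
                and track_seconds >= min_track_seconds:
            break
        s_seed, i_seed = (int(x) for x in child.generate_state(2) % (2**31))
        truth = simulate_tracks(replace(swimmer, seed=s_seed), imaging)
        frames = render_frames(truth, replace(imaging, seed=i_seed))
        m = process_stack(frames, imaging, detection, link_params, tumble, group)
        chunks.append(m)
        n_swimmers += len(truth)
        track_seconds += float(m["duration_s"].sum())
        n_videos += 1
        log.info("video %d: %d tracks, cum %.0f track-seconds / %d swimmers",
                 n_videos, len(m), track_seconds, n_swimmers)
    else:
        log.warning("run_capillary_assay hit max_videos=%d before targets", max_videos)

    metrics = pd.concat(chunks, ignore_index=True) if chunks else metrics_table(
        [], imaging.pixel_size, imaging.fps, tumble)
    return CapillaryResult(metrics, n_swimmers, track_seconds, n_videos)
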