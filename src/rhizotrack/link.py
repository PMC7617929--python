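"""Frame-to-frame track linking by optimal assignment.

Per frame pair the pairing of active tracks to new detections minimises the
total squared displacement among links shorter than the gate (max_disp per
frame of gap), with a fixed no-match penalty of max_disp² per unmatched point
— the standard gated bipartite formulation, solved exactly.  A track survives
up to ``memory`` unmatched frames; positions across a closed gap are linearly
interpolated and flagged so downstream tumble detection can skip them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["LinkParams", "Track", "link_detections", "filter_tracks",
           "frame_assignment", "default_link_params", "tracks_to_dataframe"]

log = logging.getLogger(__name__)

_BIG = 1e12


@dataclass(frozen=True)
class LinkParams:
    max_disp: float             # px per frame interval
    memory: int = 1             # frames a track persists unmatched
    min_track_len: int = 10     # frames
    min_net_disp: float = 5.0   # px, immobile-debris filter

    def __post_init__(self) -> None:
        if not self.max_disp > 0:
            raise ValueError("max_disp: must be > 0")
        if self.memory < 0:
            raise ValueError("memory: must be >= 0")
        if self.min_track_len < 2:
            raise ValueError("min_track_len: must be >= 2")


def default_link_params(swimmer, imaging) -> LinkParams:
    """Gate = ceil(1.5 x mean step length in px), derived from configuration
    rather than hard-coded."""
    step_px = swimmer.mean_speed / imaging.fps / imaging.pixel_size
    return LinkParams(max_disp=float(math.ceil(1.5 * step_px)))


@dataclass
class Track:
    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    is_gap: np.ndarray = field(default=None)
    #: another particle sat within the linking gate around this point, so the
    #: identity of the link is not trustworthy here (crossing / near-merge)
    is_contested: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.is_gap is None:
            self.is_gap = np.zeros(self.frames.size, dtype=bool)
        if self.is_contested is None:
            self.is_contested = np.zeros(self.frames.size, dtype=bool)

    @property
    def n_points(self) -> int:
        return int(self.frames.size)

    @property
    def net_displacement(self) -> float:
        return float(math.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))


def frame_assignment(prev: np.ndarray, curr: np.ndarray, max_disp: float,
                     gates: np.ndarray | None = None,
                     row_scale: np.ndarray | None = None):
    """Optimal gated assignment between two point sets.

    Returns (pairs, cost): ``pairs`` is a list of (i, j) links and ``cost``
    the objective value — sum of squared link distances plus max_disp² for
    every unmatched point on either side.  ``gates`` optionally widens the
    per-row gate and ``row_scale`` down-weights link costs per row (both used
    when a track bridges a multi-frame gap, so a gap link is judged by its
    per-frame-equivalent squared displacement).
    """
    prev = np.asarray(prev, dtype=float).reshape(-1, 2)
    curr = np.asarray(curr, dtype=float).reshape(-1, 2)
    n, m = len(prev), len(curr)
    pen = max_disp * max_disp
    if n == 0 or m == 0:
        return [], (n + m) * pen
    if gates is None:
        gates = np.full(n, max_disp)
    d2 = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(axis=2)
    allowed = d2 <= (np.asarray(gates)[:, None]) ** 2
    if row_scale is not None:
        d2 = d2 * np.asarray(row_scale, dtype=float)[:, None]
    C = np.full((n + m, n + m), _BIG)
    C[:n, :m] = np.where(allowed, d2, _BIG)
    C[:n, m:] = _BIG
    C[n:, :m] = _BIG
    C[np.arange(n), m + np.arange(n)] = pen       # track left unmatched
    C[n + np.arange(m), np.arange(m)] = pen       # detection starts new track
    C[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(C)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)
             if r < n and c < m and C[r, c] < _BIG]
    cost = float(sum(C[r, c] for r, c in zip(rows, cols) if C[r, c] < _BIG))
    return pairs, cost


class _Open:
    __slots__ = ("frames", "x", "y", "gap", "last_frame", "order")

    def __init__(self, frame, x, y, order):
        self.frames = [frame]
        self.x = [x]
        self.y = [y]
        self.gap = [False]
        self.last_frame = frame
        self.order = order


def link_detections(detections: pd.DataFrame, params: LinkParams) -> list[Track]:
    """Assemble a per-frame detection table (columns frame, x_px, y_px,
    sorted by frame) into tracks.  Track ids follow order of first
    appearance."""
    needed = {"frame", "x_px", "y_px"}
    if not needed.issubset(detections.columns):
        raise ValueError(f"detection table must have columns {sorted(needed)}")
    fr = detections["frame"].to_numpy()
    if fr.size and np.any(np.diff(fr) < 0):
        raise ValueError("detection table must be sorted by frame")

    open_tracks: list[_Open] = []
    closed: list[_Open] = []
    counter = 0
    if fr.size == 0:
        return []
    xs = detections["x_px"].to_numpy(dtype=float)
    ys = detections["y_px"].to_numpy(dtype=float)
    frames_present = np.unique(fr).astype(int)
    f_lo, f_hi = int(frames_present[0]), int(frames_present[-1])
    by_frame = {int(f): np.nonzero(fr == f)[0] for f in frames_present}

    for f in range(f_lo, f_hi + 1):
        # retire tracks that outlived their memory
        still = []
        for tr in open_tracks:
            if f - tr.last_frame > params.memory + 1:
                closed.append(tr)
            else:
                still.append(tr)
        open_tracks = still

        idx = by_frame.get(f, np.array([], dtype=int))
        pts = np.column_stack([xs[idx], ys[idx]]) if idx.size else np.empty((0, 2))
        if open_tracks and idx.size:
            prev = np.array([[tr.x[-1], tr.y[-1]] for tr in open_tracks])
            gaps = np.array([f - tr.last_frame for tr in open_tracks], dtype=float)
            pairs, _ = frame_assignment(prev, pts, params.max_disp,
                                        gates=params.max_disp * gaps,
                                        row_scale=1.0 / gaps)
        else:
            pairs = []
        matched_tracks = set()
        matched_dets = set()
        for i, j in pairs:
            tr = open_tracks[i]
            gap = f - tr.last_frame
            if gap > 1:  # close the gap with flagged, linearly interpolated points
                x0, y0 = tr.x[-1], tr.y[-1]
                for g in range(1, gap):
                    w = g / gap
                    tr.frames.append(tr.last_frame + g)
                    tr.x.append(x0 + w * (pts[j, 0] - x0))
                    tr.y.append(y0 + w * (pts[j, 1] - y0))
                    tr.gap.append(True)
            tr.frames.append(f)
            tr.x.append(float(pts[j, 0]))
            tr.y.append(float(pts[j, 1]))
            tr.gap.append(False)
            tr.last_frame = f
            matched_tracks.add(i)
            matched_dets.add(j)
        for j in range(idx.size):
            if j not in matched_dets:
                open_tracks.append(_Open(f, float(pts[j, 0]), float(pts[j, 1]), counter))
                counter += 1
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr.order)
    tracks = [
        Track(tid, np.asarray(tr.frames, dtype=int), np.asarray(tr.x),
              np.asarray(tr.y), np.asarray(tr.gap, dtype=bool))
        for tid, tr in enumerate(closed)
    ]
    _mark_contested(tracks, params.max_disp)
    return tracks


def _mark_contested(tracks: list[Track], radius: float) -> None:
    """Flag track points with a foreign particle within ``radius`` at the
    same or an adjacent frame.

    Position-only gated assignment cannot guarantee identity through such
    encounters (two candidates inside one gate), so downstream tumble
    detection treats these points like gap points: a crossing partner
    masquerades as a sharp turn.
    """
    from scipy.spatial import cKDTree

    by_frame: dict[int, list[tuple[float, float, int]]] = {}
    for tr in tracks:
        for f, x, y, g in zip(tr.frames, tr.x, tr.y, tr.is_gap):
            if not g:
                by_frame.setdefault(int(f), []).append((x, y, tr.track_id))
    trees = {}
    for f, pts in by_frame.items():
        arr = np.asarray(pts)
        trees[f] = (cKDTree(arr[:, :2]), arr[:, 2].astype(int))
    for tr in tracks:
        for i, (f, x, y) in enumerate(zip(tr.frames, tr.x, tr.y)):
            for df in (-1, 0, 1):
                ent = trees.get(int(f) + df)
                if ent is None:
                    continue
                tree, ids = ent
                hit = [j for j in tree.query_ball_point([x, y], radius)
                       if ids[j] != tr.track_id]
                if hit:
                    tr.is_contested[i] = True
                    break


def filter_tracks(tracks: list[Track], params: LinkParams) -> list[Track]:
    """Quality control before metrics: drop short tracks and immobile debris.
    Logs how many tracks each rule removed."""
    kept, n_short, n_still = [], 0, 0
    for tr in tracks:
        if tr.n_points < params.min_track_len:
            n_short += 1
        elif tr.net_displacement < params.min_net_disp:
            n_still += 1
        else:
            kept.append(tr)
    log.info("filter_tracks: kept %d, dropped %d short (<%d frames) and %d immobile (<%g px)",
             len(kept), n_short, params.min_track_len, n_still, params.min_net_disp)
    return kept


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    if not tracks:
        return pd.DataFrame(columns=["track_id", "frame", "x_px", "y_px",
                                     "is_gap", "is_contested"])
    return pd.concat(
        [pd.DataFrame({"track_id": tr.track_id, "frame": tr.frames,
                       "x_px": tr.x, "y_px": tr.y, "is_gap": tr.is_gap,
                       "is_contested": tr.is_contested})
         for tr in tracks],
        ignore_index=True,
    )
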