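"""Synthetic inputs with ground truth for every downstream analysis stage.

Four generators, mirroring the four kinds of raw data in a rhizobial
motility/symbiosis study:

* 2-D run-and-tumble swimmers rendered as diffraction-limited spots on a noisy
  camera background (capillary video stand-in),
* sigmoidal halo-diameter vs. log-concentration tables with replicate noise,
* two overlapping bivariate scatter populations (bacteria vs. bacteroids)
  with a fluorescence channel,
* root-like colour photographs bearing compact stained nodule blobs.

Each generator is deterministic given its seed, and each returns (or writes
alongside its output) the ground truth needed for recovery testing.

The swimmer model: each cell keeps a constant intrinsic speed drawn from
Normal(mean_speed, speed_sd) truncated below at 0.1*mean_speed; its heading
performs rotational diffusion during runs and is redrawn at tumble events,
which arrive as a Poisson process.  Cells leaving the field of view are
truncated there (a camera loses them), not wrapped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import halo as _halo

__all__ = [
    "SwimmerParams",
    "ImagingParams",
    "TrueCellTrack",
    "GroundTruthTrackSet",
    "simulate_tracks",
    "render_frames",
    "render_video",
    "write_stack",
    "read_stack",
    "generate_halo_table",
    "generate_cytometry_events",
    "generate_nodule_image",
    "DEFAULT_HALO_SCENARIO",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class SwimmerParams:
    """Generative motility parameters for one population of swimmers.

    Speeds in μm/s, tumble rate in events/s, rotational diffusion in rad²/s,
    field of view in μm.  ``tumble_angle_spread`` is the von-Mises
    concentration of the reorientation angle about the incoming heading;
    0 means uniform reorientation.
    """

    n_cells: int = 200
    mean_speed: float = 44.0
    speed_sd: float = 7.0
    tumble_rate: float = 0.11
    tumble_angle_spread: float = 0.0
    rot_diffusion: float = 0.062
    duration: float = 30.0
    fov_width: float = 288.0
    fov_height: float = 216.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells", "must be >= 1")
        _require(math.isfinite(self.mean_speed) and self.mean_speed > 0,
                 "mean_speed", "must be finite and > 0")
        _require(math.isfinite(self.speed_sd) and self.speed_sd >= 0,
                 "speed_sd", "must be finite and >= 0")
        _require(math.isfinite(self.tumble_rate) and self.tumble_rate >= 0,
                 "tumble_rate", "must be finite and >= 0")
        _require(self.tumble_angle_spread >= 0, "tumble_angle_spread", "must be >= 0")
        _require(math.isfinite(self.rot_diffusion) and self.rot_diffusion >= 0,
                 "rot_diffusion", "must be finite and >= 0")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.fov_width > 0 and self.fov_height > 0,
                 "fov_width/fov_height", "must be > 0")


@dataclass(frozen=True)
class ImagingParams:
    """Camera/optics model.  Defaults follow the study's acquisition
    (1440 x 1080 px at 10 fps) with a plausible 40x calibration of
    0.2 μm/px."""

    fps: float = 10.0
    pixel_size: float = 0.2
    frame_width: int = 1440
    frame_height: int = 1080
    psf_sigma: float = 1.3
    spot_amplitude: float = 400.0
    background_level: float = 100.0
    noise_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.fps > 0, "fps", "must be > 0")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.frame_width >= 16 and self.frame_height >= 16,
                 "frame_width/frame_height", "must be >= 16 px")
        _require(self.psf_sigma > 0, "psf_sigma", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")

    @property
    def fov_width_um(self) -> float:
        return self.frame_width * self.pixel_size

    @property
    def fov_height_um(self) -> float:
        return self.frame_height * self.pixel_size

    def matched_fov(self, swimmer: SwimmerParams) -> SwimmerParams:
        """Swimmer params whose FOV exactly covers this camera frame."""
        return replace(swimmer, fov_width=self.fov_width_um,
                       fov_height=self.fov_height_um)


@dataclass
class TrueCellTrack:
    """Ground-truth record for one cell: frame indices are 0..len-1 until the
    cell leaves the FOV; ``tumble_frames`` are the frames at which the heading
    was redrawn."""

    cell_id: int
    frames: np.ndarray          # strictly increasing, starts at 0
    x_um: np.ndarray
    y_um: np.ndarray
    speed: float
    tumble_frames: np.ndarray

    @property
    def n_points(self) -> int:
        return int(self.frames.size)


@dataclass
class GroundTruthTrackSet:
    cells: list[TrueCellTrack]
    params: SwimmerParams

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_frames(self) -> int:
        return int(max(c.frames[-1] for c in self.cells) + 1)

    def total_tumbles(self) -> int:
        return int(sum(c.tumble_frames.size for c in self.cells))

    def total_time(self, fps: float) -> float:
        """Observed cell-time in seconds (sum of per-cell step counts / fps)."""
        return float(sum(c.n_points - 1 for c in self.cells)) / fps

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"cell_id": c.cell_id, "frame": c.frames,
                          "x_um": c.x_um, "y_um": c.y_um})
            for c in self.cells
        ]
        return pd.concat(rows, ignore_index=True)


def simulate_tracks(params: SwimmerParams, imaging: ImagingParams) -> GroundTruthTrackSet:
    """Simulate run-and-tumble trajectories sampled at the camera frame rate.

    The timestep is 1/fps.  At each step a cell first (possibly) tumbles —
    heading redrawn, frame recorded — then accrues rotational diffusion, then
    advances by speed/fps along its heading.  A cell whose next position falls
    outside the FOV ends its record at the last in-FOV frame.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    dt = 1.0 / imaging.fps
    n_frames = max(int(round(params.duration * imaging.fps)), 1)

    # per-cell constant speeds: truncated normal, lower bound 0.1*mean
    lo = 0.1 * params.mean_speed
    speeds = rng.normal(params.mean_speed, params.speed_sd, size=n)
    for _ in range(100):
        bad = speeds < lo
        if not bad.any():
            break
        speeds[bad] = rng.normal(params.mean_speed, params.speed_sd, size=bad.sum())
    np.clip(speeds, lo, None, out=speeds)

    x = rng.uniform(0.0, params.fov_width, size=n)
    y = rng.uniform(0.0, params.fov_height, size=n)
    theta = rng.uniform(-np.pi, np.pi, size=n)

    xs = np.full((n_frames, n), np.nan)
    ys = np.full((n_frames, n), np.nan)
    xs[0], ys[0] = x, y
    end = np.full(n, n_frames - 1, dtype=int)   # last recorded frame per cell
    tumbles: list[list[int]] = [[] for _ in range(n)]

    p_tumble = 1.0 - math.exp(-params.tumble_rate * dt)
    diff_sd = math.sqrt(params.rot_diffusion * dt)
    active = np.ones(n, dtype=bool)

    for t in range(n_frames - 1):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        # tumble: Poisson arrival per step, heading redrawn at this frame
        tumbling = rng.random(idx.size) < p_tumble
        if tumbling.any():
            who = idx[tumbling]
            if params.tumble_angle_spread == 0:
                theta[who] = rng.uniform(-np.pi, np.pi, size=who.size)
            else:
                theta[who] = rng.vonmises(theta[who], params.tumble_angle_spread)
            for w in who:
                tumbles[w].append(t)
        # rotational diffusion during the run
        if diff_sd > 0:
            theta[idx] += rng.normal(0.0, diff_sd, size=idx.size)
        step = speeds[idx] * dt
        nx = x[idx] + step * np.cos(theta[idx])
        ny = y[idx] + step * np.sin(theta[idx])
        inside = (nx >= 0) & (nx <= params.fov_width) & (ny >= 0) & (ny <= params.fov_height)
        exiting = idx[~inside]
        end[exiting] = t
        active[exiting] = False
        stay = idx[inside]
        x[stay], y[stay] = nx[inside], ny[inside]
        xs[t + 1, stay] = x[stay]
        ys[t + 1, stay] = y[stay]

    cells = []
    for i in range(n):
        m = end[i] + 1
        tf = np.array([f for f in tumbles[i] if f <= end[i] - 1], dtype=int)
        cells.append(TrueCellTrack(i, np.arange(m), xs[:m, i].copy(),
                                   ys[:m, i].copy(), float(speeds[i]), tf))
    return GroundTruthTrackSet(cells, params)


# ---------------------------------------------------------------------------
# video rendering

def render_frames(tracks: GroundTruthTrackSet, imaging: ImagingParams,
                  n_frames: int | None = None) -> np.ndarray:
    """Render a (T, H, W) uint16 stack: background + one Gaussian spot per
    in-FOV cell + additive Gaussian noise.

    ``n_frames`` defaults to the last frame holding an active cell; passing a
    value smaller than a track's reach is rejected.
    """
    last = tracks.n_frames
    if n_frames is None:
        n_frames = last
    elif last > n_frames:
        raise ValueError(
            f"tracks reference frame {last - 1}, beyond the requested {n_frames} frames"
        )
    H, W = imaging.frame_height, imaging.frame_width
    rng = np.random.default_rng(imaging.seed)
    sig = imaging.psf_sigma
    R = int(math.ceil(4 * sig))
    off = np.arange(-R, R + 1, dtype=np.float32)

    # gather (frame, x_px, y_px) once
    per_frame: list[list[tuple[float, float]]] = [[] for _ in range(n_frames)]
    for c in tracks:
        px = c.x_um / imaging.pixel_size - 0.5
        py = c.y_um / imaging.pixel_size - 0.5
        for f, cx, cy in zip(c.frames, px, py):
            per_frame[f].append((cx, cy))

    out = np.empty((n_frames, H, W), dtype=np.uint16)
    frame = np.empty((H, W), dtype=np.float32)
    for t in range(n_frames):
        frame.fill(imaging.background_level)
        for cx, cy in per_frame[t]:
            ic, ir = int(round(cx)), int(round(cy))
            gx = np.exp(-((off + ic - cx) ** 2) / (2 * sig * sig))
            gy = np.exp(-((off + ir - cy) ** 2) / (2 * sig * sig))
            r0, r1 = max(ir - R, 0), min(ir + R + 1, H)
            c0, c1 = max(ic - R, 0), min(ic + R + 1, W)
            patch = np.outer(gy[r0 - (ir - R): r1 - (ir - R)],
                             gx[c0 - (ic - R): c1 - (ic - R)])
            frame[r0:r1, c0:c1] += imaging.spot_amplitude * patch
        if imaging.noise_sd > 0:
            frame += rng.standard_normal((H, W), dtype=np.float32) * imaging.noise_sd
        np.clip(frame, 0, 65535, out=frame)
        out[t] = frame.astype(np.uint16)
    return out


def write_stack(frames: np.ndarray, path: str | Path, imaging: ImagingParams) -> Path:
    """Write a multi-page 16-bit TIFF plus a sidecar JSON with the metadata
    the tracking pipeline needs (fps, μm/px, frame size, seed)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {"fps": imaging.fps, "pixel_size_um": imaging.pixel_size,
            "width": int(frames.shape[2]), "height": int(frames.shape[1]),
            "seed": imaging.seed}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    import tifffile

    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return frames, meta


def render_video(tracks: GroundTruthTrackSet, imaging: ImagingParams,
                 path: str | Path, n_frames: int | None = None) -> Path:
    """Render and write a capillary-style recording (TIFF + JSON sidecar)."""
    return write_stack(render_frames(tracks, imaging, n_frames), path, imaging)


# ---------------------------------------------------------------------------
# halo dose-response tables

@dataclass(frozen=True)
class HaloCurve:
    """True 4PL curve (b, c, d, e) used to draw one strain x carbon series."""

    b: float
    c: float
    d: float
    e: float

    def __call__(self, conc):
        return _halo.four_pl(conc, self.b, self.c, self.d, self.e)


#: Study-like scenario: wildtype halos shrink ~20% on glucose, ~30% on
#: pyruvate and ~70% on succinate over 1-30 mM; a che1-like mutant makes small
#: halos with little dose response; the fliG-like control is non-motile (flat
#: 6 mm colony), matching the convergence of all strains at high succinate.
DEFAULT_HALO_SCENARIO: dict[tuple[str, str], HaloCurve] = {
    ("wildtype", "glucose"): HaloCurve(1.5, 28.0, 35.0, 6.0),
    ("wildtype", "pyruvate"): HaloCurve(1.5, 26.0, 38.0, 8.0),
    ("wildtype", "succinate"): HaloCurve(2.0, 12.0, 40.0, 8.0),
    ("che1", "glucose"): HaloCurve(1.5, 14.0, 16.0, 6.0),
    ("che1", "pyruvate"): HaloCurve(1.5, 13.0, 16.0, 8.0),
    ("che1", "succinate"): HaloCurve(2.0, 9.0, 16.0, 8.0),
    ("fliG", "glucose"): HaloCurve(1.0, 6.0, 6.0, 8.0),
    ("fliG", "pyruvate"): HaloCurve(1.0, 6.0, 6.0, 8.0),
    ("fliG", "succinate"): HaloCurve(1.0, 6.0, 6.0, 8.0),
}

DEFAULT_CONCENTRATIONS = (1.0, 2.0, 5.0, 10.0, 20.0, 30.0)


def generate_halo_table(curves: dict[tuple[str, str], HaloCurve] | None = None,
                        concentrations=DEFAULT_CONCENTRATIONS,
                        noise_sd: float = 1.5, replicates: int = 3,
                        seed: int = 0) -> pd.DataFrame:
    """Draw halo diameters as 4PL(conc) + Normal(0, noise_sd) per replicate.

    Columns: strain, carbon_source, conc_mM, diameter_mm, replicate.
    """
    _require(noise_sd >= 0, "noise_sd", "must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    _require(bool(np.all(conc > 0)), "concentrations", "must be > 0")
    if curves is None:
        curves = DEFAULT_HALO_SCENARIO
    rng = np.random.default_rng(seed)
    rows = []
    for (strain, carbon), curve in curves.items():
        truth = curve(conc)
        for rep in range(1, replicates + 1):
            noisy = truth + rng.normal(0.0, noise_sd, size=conc.size)
            rows.append(pd.DataFrame({
                "strain": strain, "carbon_source": carbon, "conc_mM": conc,
                "diameter_mm": np.clip(noisy, 0.0, None), "replicate": rep,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# flow-cytometry event mixtures

def generate_cytometry_events(
    n_bacteria: int,
    n_bacteroids: int,
    bacteria_mean=(200.0, 150.0),
    bacteroid_mean=(600.0, 450.0),
    bacteria_cov=((3600.0, 900.0), (900.0, 2500.0)),
    bacteroid_cov=((10000.0, 2500.0), (2500.0, 8100.0)),
    fl_mean: float = 1200.0,
    fl_sd: float = 200.0,
    n_debris: int = 0,
    debris_fl: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bivariate (FSC, SSC) mixture of labelled bacteria and bacteroids plus
    optional dim debris; returns (events, truth) row-aligned DataFrames.

    Bacteroids must sit above bacteria in both scatter channels (they are
    larger and more granular); the generator refuses any other ordering.
    """
    bm, dm = np.asarray(bacteria_mean, float), np.asarray(bacteroid_mean, float)
    if not np.all(dm > bm):
        raise ValueError(
            "bacteroid_mean must exceed bacteria_mean in both FSC and SSC "
            f"(got bacteria {bm.tolist()}, bacteroid {dm.tolist()}): bacteroids "
            "are larger and more granular than undifferentiated bacteria"
        )
    for name, cov in (("bacteria_cov", bacteria_cov), ("bacteroid_cov", bacteroid_cov)):
        if np.any(np.linalg.eigvalsh(np.asarray(cov, float)) <= 0):
            raise ValueError(f"{name}: covariance must be positive-definite")
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for count, mean, cov, label in (
        (n_bacteria, bm, bacteria_cov, "bacteria"),
        (n_bacteroids, dm, bacteroid_cov, "bacteroid"),
    ):
        if count:
            sc = rng.multivariate_normal(mean, np.asarray(cov, float), size=count)
            fl = rng.normal(fl_mean, fl_sd, size=count)
            parts.append(np.column_stack([sc, fl]))
            labels += [label] * count
    if n_debris:
        sc = rng.multivariate_normal(bm * 0.4, np.asarray(bacteria_cov, float), size=n_debris)
        fl = rng.normal(debris_fl, debris_fl * 0.4, size=n_debris)
        parts.append(np.column_stack([sc, fl]))
        labels += ["debris"] * n_debris
    data = np.clip(np.concatenate(parts, axis=0), 0.0, None)
    order = rng.permutation(data.shape[0])
    events = pd.DataFrame(data[order], columns=["fsc", "ssc", "fl"])
    truth = pd.DataFrame({"true_label": np.asarray(labels, dtype=object)[order]})
    return events, truth


# ---------------------------------------------------------------------------
# stained-root nodule images

_STAIN_RGB = {"xgal": (45, 110, 125), "magenta": (165, 45, 115)}


@dataclass
class NoduleImage:
    image: np.ndarray           # (H, W, 3) uint8
    n_nodules: int
    centers: np.ndarray         # (n, 2) row, col
    radii: np.ndarray


def generate_nodule_image(n_nodules: int, radius_range=(8.0, 14.0),
                          stain: str = "xgal", canvas=(900, 1200),
                          seed: int = 0, max_tries: int = 200) -> NoduleImage:
    """Root-coloured textured background plus ``n_nodules`` compact stained
    ellipses, placed non-merging (centre distance >= 1.5 x max radius) and
    fully inside the canvas."""
    if stain not in _STAIN_RGB:
        raise ValueError(f"stain: unknown preset {stain!r}, choose from {sorted(_STAIN_RGB)}")
    r_lo, r_hi = radius_range
    _require(0 < r_lo <= r_hi, "radius_range", "must satisfy 0 < min <= max")
    H, W = canvas
    rng = np.random.default_rng(seed)

    from scipy.ndimage import gaussian_filter

    base = np.array([150.0, 122.0, 92.0])          # dry root / vermiculite tone
    texture = gaussian_filter(rng.standard_normal((H, W)), 25.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    grain = rng.standard_normal((H, W)) * 0.02
    shade = 1.0 + 0.10 * texture + grain
    img = base[None, None, :] * shade[:, :, None]

    margin = r_hi + 2.0
    # two max-radius blobs must not touch even after morphological closing
    # downstream, so keep centres a full diameter plus a small guard apart
    min_dist = max(1.5 * r_hi, 2.0 * r_hi + 5.0)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n_nodules):
        for _attempt in range(max_tries):
            r = rng.uniform(margin, H - margin)
            c = rng.uniform(margin, W - margin)
            if all((r - rr) ** 2 + (c - cc) ** 2 >= min_dist ** 2 for rr, cc in centers):
                centers.append((r, c))
                radii.append(rng.uniform(r_lo, r_hi))
                break
        else:
            raise ValueError(
                f"could not place {n_nodules} non-merging nodules of radius "
                f"<= {r_hi} px on a {H}x{W} canvas after {max_tries} tries "
                "(centre distance >= 1.5 x max radius required)"
            )

    color = np.array(_STAIN_RGB[stain], dtype=float)
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    for (cr, cc), rad in zip(centers, radii):
        b = rad * rng.uniform(0.7, 1.0)
        ang = rng.uniform(0.0, np.pi)
        jitter = rng.uniform(0.9, 1.1, size=3)
        r0, r1 = int(cr - rad - 3), int(cr + rad + 4)
        c0, c1 = int(cc - rad - 3), int(cc + rad + 4)
        dy = rows[r0:r1] - cr
        dx = cols[:, c0:c1] - cc
        u = dy * math.cos(ang) + dx * math.sin(ang)
        v = -dy * math.sin(ang) + dx * math.cos(ang)
        dist = np.sqrt((u / rad) ** 2 + (v / b) ** 2)
        alpha = np.clip((1.1 - dist) / 0.2, 0.0, 1.0)   # soft 1-2 px rim
        patch = img[r0:r1, c0:c1, :]
        patch *= (1.0 - alpha[:, :, None])
        patch += alpha[:, :, None] * (color * jitter)[None, None, :]

    out = np.clip(img, 0, 255).astype(np.uint8)
    return NoduleImage(out, n_nodules, np.array(centers).reshape(-1, 2),
                       np.array(radii))
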