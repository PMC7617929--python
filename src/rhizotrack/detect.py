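"""Subpixel spot detection for bacteria imaged as diffraction-limited spots.

The classic particle-locating recipe: estimate and subtract the slowly-varying
background, band-pass filter at the spot scale, keep thresholded local maxima
separated by a minimum distance, and refine each to an intensity-weighted
centroid.  Coordinates are 0-based with pixel centres at integer positions,
origin at the top-left pixel centre, x = column and y = row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter

__all__ = ["DetectionParams", "detect_spots", "detect_stack",
           "default_detection_params", "filtered_peak_fraction"]

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["frame", "x_px", "y_px", "intensity", "diameter_px"]


@dataclass(frozen=True)
class DetectionParams:
    """Feature-size band in pixels, intensity threshold (in band-passed units
    above local background), minimum peak separation, and the odd window used
    for centroid refinement."""

    bandpass_low: float = 1.0
    bandpass_high: float = 4.0
    threshold: float = 50.0
    min_separation: int = 5
    refine_window: int = 9

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ValueError("bandpass: need 0 < bandpass_low < bandpass_high")
        if self.refine_window < 3 or self.refine_window % 2 == 0:
            raise ValueError("refine_window: must be odd and >= 3")
        if self.min_separation < 1:
            raise ValueError("min_separation: must be >= 1")


def filtered_peak_fraction(psf_sigma: float, params: DetectionParams) -> float:
    """Fraction of a Gaussian spot's peak amplitude surviving the band-pass.

    A Gaussian of width s convolved with a Gaussian of width t keeps peak
    fraction s²/(s²+t²); the band-pass is the difference of two such blurs.
    """
    s2 = psf_sigma**2
    return s2 / (s2 + params.bandpass_low**2) - s2 / (s2 + params.bandpass_high**2)


def default_detection_params(imaging) -> DetectionParams:
    """Detection parameters derived from the imaging configuration.

    Threshold = 25% of the expected band-passed spot peak — far above the
    filtered camera-noise floor at the default SNR of 10, far below real spots.
    """
    base = DetectionParams()
    peak = imaging.spot_amplitude * filtered_peak_fraction(imaging.psf_sigma, base)
    sep = max(3, int(round(3 * imaging.psf_sigma)))
    return DetectionParams(threshold=0.25 * peak, min_separation=sep,
                           refine_window=2 * int(math.ceil(3 * imaging.psf_sigma)) + 1)


def _bandpass(img: np.ndarray, p: DetectionParams) -> np.ndarray:
    img = np.ascontiguousarray(img, dtype=np.float32)
    bg_size = 2 * int(round(4 * p.bandpass_high)) + 1
    x = img - uniform_filter(img, size=bg_size)
    high_size = 2 * int(round(p.bandpass_high)) + 1
    return gaussian_filter(x, p.bandpass_low) - uniform_filter(x, size=high_size)


def _refine(filtered: np.ndarray, r: int, c: int, w: int):
    """Intensity-weighted centroid within an odd window; one recentring pass.
    Returns None when the window would leave the image (edge spots are
    unreliable and dropped)."""
    h = w // 2
    H, W = filtered.shape
    for _ in range(2):
        if not (h <= r < H - h and h <= c < W - h):
            return None
        win = np.clip(filtered[r - h:r + h + 1, c - h:c + h + 1], 0.0, None)
        tot = float(win.sum())
        if tot <= 0:
            return None
        iy = np.arange(-h, h + 1, dtype=np.float64)
        cy = float((win.sum(axis=1) @ iy) / tot)
        cx = float((win.sum(axis=0) @ iy) / tot)
        if abs(cy) <= 0.6 and abs(cx) <= 0.6:
            var = float(((win.sum(axis=1) @ (iy - cy) ** 2)
                         + (win.sum(axis=0) @ (iy - cx) ** 2)) / tot) / 2.0
            return r + cy, c + cx, tot, 2.0 * math.sqrt(max(var, 0.0))
        r += int(round(cy))
        c += int(round(cx))
    return None


def _detect_one(filtered: np.ndarray, p: DetectionParams) -> list[tuple]:
    size = p.min_separation if p.min_separation % 2 else p.min_separation + 1
    h = size // 2
    H, W = filtered.shape
    rr, cc = np.nonzero(filtered > p.threshold)
    if rr.size == 0:
        return []
    inner = (rr >= h) & (rr < H - h) & (cc >= h) & (cc < W - h)
    rr, cc = rr[inner], cc[inner]
    # local-maximum test only at above-threshold pixels (sparse, so cheaper
    # than a dense maximum filter at video scale)
    keep = np.ones(rr.size, dtype=bool)
    centre = filtered[rr, cc]
    for dr in range(-h, h + 1):
        for dc in range(-h, h + 1):
            if dr == 0 and dc == 0:
                continue
            keep &= centre >= filtered[rr + dr, cc + dc]
    rr, cc = rr[keep], cc[keep]
    if rr.size == 0:
        return []
    vals = filtered[rr, cc]
    # deterministic tie-break: brighter first, then smaller (y, x)
    order = np.lexsort((cc, rr, -vals))
    kept_r, kept_c, out = [], [], []
    min2 = p.min_separation**2
    for i in order:
        r, c = int(rr[i]), int(cc[i])
        if any((r - kr) ** 2 + (c - kc) ** 2 < min2 for kr, kc in zip(kept_r, kept_c)):
            continue
        kept_r.append(r)
        kept_c.append(c)
        ref = _refine(filtered, r, c, p.refine_window)
        if ref is None:
            continue
        y, x, inten, diam = ref
        # noise can raise two raw maxima on one spot's flanks; their refined
        # centroids collapse onto the spot centre, so dedupe again after
        # refinement (brightest wins; candidates are visited brightest-first)
        if any((x - ox) ** 2 + (y - oy) ** 2 < min2 for ox, oy, *_ in out):
            continue
        out.append((x, y, inten, diam))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def detect_spots(frame: np.ndarray, params: DetectionParams) -> pd.DataFrame:
    """Locate spots in a single 2-D image.

    Returns a DataFrame with columns x_px, y_px, intensity, diameter_px,
    sorted by (y, x).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"detect_spots expects a 2-D image, got shape {frame.shape}")
    if params.refine_window > min(frame.shape):
        raise ValueError("refine_window larger than the image")
    rows = _detect_one(_bandpass(frame, params), params)
    return pd.DataFrame(rows, columns=["x_px", "y_px", "intensity", "diameter_px"])


def detect_stack(stack, params: DetectionParams) -> pd.DataFrame:
    """Run detection over a frame stack (array of shape (T, H, W) or a path
    to a TIFF written by the simulator); concatenates per-frame detections
    with a leading ``frame`` column."""
    if isinstance(stack, (str, bytes)) or hasattr(stack, "__fspath__"):
        from .swim_sim import read_stack

        stack, _ = read_stack(stack)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        if stack.ndim == 2 and stack.shape[0] == 0:  # empty stack
            return pd.DataFrame(columns=DETECTION_COLUMNS)
        raise ValueError(f"detect_stack expects (T, H, W), got shape {stack.shape}")
    chunks = []
    for t in range(stack.shape[0]):
        try:
            rows = _detect_one(_bandpass(stack[t], params), params)
        except Exception as err:
            raise RuntimeError(f"detection failed at frame {t}: {err}") from err
        if rows:
            arr = np.asarray(rows, dtype=float)
            chunks.append(np.column_stack([np.full(len(rows), t, dtype=float), arr]))
        if (t + 1) % 100 == 0:
            log.info("detected %d frames", t + 1)
    if not chunks:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    return pd.DataFrame(np.concatenate(chunks), columns=DETECTION_COLUMNS)
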