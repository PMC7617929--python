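"""Counting stained nodules in root photographs by colour segmentation.

Pixels are classified in hue/saturation/value space against a stain preset
(blue-green X-gal-like or magenta GlcA-like), the mask is closed
morphologically, 8-connected components are extracted (optionally split by a
distance-transform watershed when nodules touch) and regions are kept if
their area lies inside [min_area, max_area].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

__all__ = ["SegmentationParams", "NoduleCountResult", "segment_nodules",
           "STAIN_PRESETS"]


@dataclass(frozen=True)
class SegmentationParams:
    hue_range: tuple = (0.42, 0.65)      # blue-green X-gal stain by default
    saturation_min: float = 0.25
    value_range: tuple = (0.05, 1.0)
    min_area: int = 40                   # px²
    max_area: int = 5000
    closing_radius: int = 2
    split_touching: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("areas: need 0 < min_area < max_area")
        for name, (lo, hi) in (("hue_range", self.hue_range),
                               ("value_range", self.value_range)):
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError(f"{name}: bounds must lie in [0, 1]")
        if not 0 <= self.saturation_min <= 1:
            raise ValueError("saturation_min: must lie in [0, 1]")


#: Ready-made parameter sets for the two stains used in double-stained
#: competition assays.
STAIN_PRESETS: dict[str, SegmentationParams] = {
    "xgal": SegmentationParams(hue_range=(0.42, 0.65)),
    "magenta": SegmentationParams(hue_range=(0.80, 0.97)),
}


@dataclass
class NoduleCountResult:
    image_id: str
    n_nodules: int
    regions: pd.DataFrame        # area_px2, centroid_row, centroid_col, mean RGB
    params: SegmentationParams


def _stain_mask(hsv: np.ndarray, p: SegmentationParams) -> np.ndarray:
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    lo, hi = p.hue_range
    in_hue = (h >= lo) & (h <= hi) if lo <= hi else (h >= lo) | (h <= hi)
    vlo, vhi = p.value_range
    return in_hue & (s >= p.saturation_min) & (v >= vlo) & (v <= vhi)


def segment_nodules(image: np.ndarray, params: SegmentationParams | None = None,
                    image_id: str = "") -> NoduleCountResult:
    """Count compact stained blobs in one colour image."""
    params = params or STAIN_PRESETS["xgal"]
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("segment_nodules needs a colour (H, W, 3) image; "
                         "got a greyscale or malformed array")
    rgb = image[..., :3]
    if rgb.dtype != np.uint8:
        rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    mask = _stain_mask(rgb2hsv(rgb), params)
    if params.closing_radius > 0:
        mask = ndi.binary_closing(mask, structure=disk(params.closing_radius))

    if params.split_touching:
        dist = ndi.distance_transform_edt(mask)
        min_dist = max(int(round(np.sqrt(params.min_area / np.pi))), 3)
        peaks = peak_local_max(dist, labels=cc_label(mask, connectivity=2),
                               min_distance=min_dist, exclude_border=False)
        markers = np.zeros(mask.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=mask, connectivity=2)
    else:
        labels = cc_label(mask, connectivity=2)  # 8-connectivity

    rows = []
    for reg in regionprops(labels):
        if params.min_area <= reg.area <= params.max_area:
            rr, cc = reg.coords[:, 0], reg.coords[:, 1]
            mean_rgb = rgb[rr, cc].mean(axis=0)
            rows.append({
                "area_px2": int(reg.area),
                "centroid_row": float(reg.centroid[0]),
                "centroid_col": float(reg.centroid[1]),
                "mean_r": float(mean_rgb[0]),
                "mean_g": float(mean_rgb[1]),
                "mean_b": float(mean_rgb[2]),
            })
    regions = pd.DataFrame(rows, columns=["area_px2", "centroid_row",
                                          "centroid_col", "mean_r", "mean_g",
                                          "mean_b"])
    return NoduleCountResult(image_id, len(regions), regions, params)
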