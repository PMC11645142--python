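"""Per-field histology scores: positive-cell fractions, positive-area
fraction, and the trichrome blue/red area percentage.

These are the field-level readouts used for apoptosis (TUNEL), inflammation
(CD45), myofibroblast activation (alpha-SMA) and fibrosis (Masson's
trichrome) scoring.  A cell counts as marker-positive when at least
``min_overlap_frac`` of its nucleus (optionally ring-dilated, for membranous
markers such as CD45) lies inside the marker mask; area scores are simple
in-region fractions; the trichrome index classifies RGB pixels as blue
(collagen) or red (cytoplasm/muscle) by channel dominance and reports
100 * blue / red.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import expand_labels

from .images import ApicolocError, BinaryMask, ChannelImage, LabelMap
from .segmentation import _THRESHOLDERS

__all__ = [
    "FieldScore",
    "positive_cell_fraction",
    "positive_area_fraction",
    "trichrome_blue_red_percent",
]

DEFAULT_MIN_OVERLAP_FRAC = 0.5
DEFAULT_DOMINANCE = 1.2      # k_b = k_r: channel-dominance ratio
DEFAULT_SATURATION_FLOOR = 50.0  # 8-bit floor below which a pixel is unstained


@dataclass
class FieldScore:
    """One metric for one field (fraction in [0, 1] or a percentage)."""

    field_id: str
    animal_id: str
    metric: str
    value: float
    n_cells: int | None = None
    area_px: int | None = None


def positive_cell_fraction(nuclei: LabelMap, marker: BinaryMask,
                           min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
                           dilate_um: float = 0.0,
                           pixel_size_um: float = 1.0) -> float:
    """Fraction of cells whose nucleus lies (mostly) in the marker mask.

    A cell is positive when at least ``min_overlap_frac`` of its nucleus
    pixels fall inside the marker mask.  For membranous markers set
    ``dilate_um`` > 0: positivity is then judged on the nucleus ring-dilated
    by that distance.  Raises on an empty field (zero nuclei).
    """
    if nuclei.shape != marker.shape:
        raise ApicolocError("nuclei and marker mask differ in shape")
    ids = nuclei.ids()
    if ids.size == 0:
        raise ApicolocError("empty field: no nuclei")
    lab = nuclei.labels
    if dilate_um > 0:
        lab = expand_labels(lab, distance=dilate_um / pixel_size_um)
    ones = np.ones(lab.shape)
    n_px = ndimage.sum_labels(ones, lab, ids)
    n_pos = ndimage.sum_labels(marker.mask.astype(float), lab, ids)
    positive = (n_pos / n_px) >= min_overlap_frac
    return float(positive.sum() / ids.size)


def positive_area_fraction(image: ChannelImage, region: np.ndarray,
                           method: str = "otsu2") -> float:
    """Fraction of the region's pixels above the threshold.

    ``method`` is ``"otsu2"``, ``"min_cross_entropy"`` or ``"fixed:<value>"``.
    Raises on an empty region.
    """
    region = np.asarray(region, dtype=bool)
    if image.shape != region.shape:
        raise ApicolocError("image and region differ in shape")
    n_region = int(region.sum())
    if n_region == 0:
        raise ApicolocError("empty region")
    if method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    elif method in _THRESHOLDERS:
        thr = _THRESHOLDERS[method](image.pixels[region])
    else:
        raise ApicolocError(f"unknown threshold method {method!r}")
    return float((image.pixels[region] > thr).sum() / n_region)


def trichrome_blue_red_percent(rgb: np.ndarray, region: np.ndarray | None = None,
                               k_b: float = DEFAULT_DOMINANCE,
                               k_r: float = DEFAULT_DOMINANCE,
                               floor: float = DEFAULT_SATURATION_FLOOR) -> float:
    """Masson's-trichrome fibrosis index: 100 * blue area / red area.

    In-region pixels are classified as blue (collagen) when ``B > k_b * R``
    and B is above the saturation floor, red when ``R > k_r * B`` and R is
    above the floor, and neither otherwise.  Raises when no red pixels exist
    (the ratio is undefined).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ApicolocError("expected an H x W x 3 RGB image")
    if region is None:
        region = np.ones(rgb.shape[:2], dtype=bool)
    region = np.asarray(region, dtype=bool)
    r, b = rgb[..., 0], rgb[..., 2]
    blue = region & (b > k_b * r) & (b >= floor)
    red = region & (r > k_r * b) & (r >= floor)
    n_red = int(red.sum())
    if n_red == 0:
        raise ApicolocError("undefined blue/red ratio: no red pixels in region")
    return float(100.0 * blue.sum() / n_red)
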