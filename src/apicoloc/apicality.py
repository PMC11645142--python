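"""Tissue-level apicality scoring of apical-membrane cargo localization.

The score quantifies how much of a cargo protein (UMOD) sits on the apical
plasma membrane of kidney tubules versus inside the cells.  The chain is:

1. **Tissue** — blurred DAPI, two-class Otsu, hole filling, and erosion by a
   margin to drop the very peripheral edge of the section.
2. **Cortex** — the region where the proximal-tubule lectin (LTL) carries
   texture: local standard deviation of LTL in a window, Otsu on that energy,
   intersected with tissue; connected regions whose mean MUC1 exceeds a high
   papilla cutoff are excluded (the papilla is strongly MUC1-positive but is
   not cortex).
3. **Apical area** — pixels at or above a high quantile of MUC1 within the
   cortex (the apical membrane band of MUC1-positive tubules), despeckled.
4. **Tubular area** — the apical area expanded by 8 um (Euclidean distance),
   restricted to the low-MUC1-threshold image region, which excludes the
   intratubular (luminal) space.  **Intracellular area** = tubular minus
   apical.
5. **Score** — tubules are connected components of the tubular area; tubules
   whose mean cargo exceeds a positivity cutoff (Otsu over per-tubule means by
   default) are scored as ratio A/B of mean cargo in the apical (A) versus
   intracellular (B) area, and the per-section score is the mean ratio over
   positive tubules.

Quantile thresholds make the procedure invariant to the intensity scale of
the MUC1 channel, and the ratio of means makes the score invariant to any
positive gain on the cargo channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import (
    ApicolocError,
    ChannelImage,
    DegenerateInputError,
    logger,
)
from .segmentation import EIGHT, threshold_otsu2

__all__ = [
    "RegionSet",
    "SectionApicality",
    "segment_tissue",
    "find_cortex",
    "segment_apical",
    "tubular_area",
    "score_apicality",
    "score_section",
]

DEFAULT_HIGH_QUANTILE = 0.95
DEFAULT_LOW_QUANTILE = 0.50
DEFAULT_EXPAND_UM = 8.0
DEFAULT_TEXTURE_WINDOW_UM = 16.0
DEFAULT_PAPILLA_QUANTILE = 0.98
DEFAULT_MIN_PAPILLA_AREA_UM2 = 200.0
DEFAULT_MIN_SPECK_PX = 9


@dataclass
class RegionSet:
    """The masks of the apicality chain over one section.

    Invariants: apical is a subset of tubular; intracellular is exactly
    tubular minus apical; everything is within tissue.
    """

    tissue: np.ndarray
    cortex: np.ndarray
    apical: np.ndarray
    muc1_low: np.ndarray
    tubular: np.ndarray
    intracellular: np.ndarray
    pixel_size_um: float

    def validate(self) -> None:
        if np.any(self.apical & ~self.tubular):
            raise ApicolocError("apical area must lie within the tubular area")
        if np.any(self.intracellular != (self.tubular & ~self.apical)):
            raise ApicolocError("intracellular must equal tubular minus apical")


@dataclass
class SectionApicality:
    """Per-section result: mean apicality ratio over cargo-positive tubules."""

    section_id: str
    score: float
    n_tubules: int
    tubules: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Region segmentation
# ---------------------------------------------------------------------------

def segment_tissue(dapi: ChannelImage, blur_sigma_um: float = 5.0,
                   margin_um: float = 2.0) -> np.ndarray:
    """Tissue mask from blurred DAPI, excluding the peripheral edge.

    Gaussian blur, Otsu-2 threshold, hole filling, then erosion by
    ``margin_um`` (disk radius in pixels).  Raises when the erosion leaves
    nothing (margin too large for the section).
    """
    if blur_sigma_um <= 0:
        raise ApicolocError("blur_sigma_um must be positive")
    px = dapi.pixel_size_um
    blurred = ndimage.gaussian_filter(dapi.pixels, blur_sigma_um / px)
    thr = threshold_otsu2(blurred)
    mask = ndimage.binary_fill_holes(blurred > thr)
    margin_px = int(round(margin_um / px))
    if margin_px >= min(mask.shape) / 2:
        raise ApicolocError("empty tissue after erosion: margin too large")
    if margin_px > 0:
        yy, xx = np.mgrid[-margin_px : margin_px + 1, -margin_px : margin_px + 1]
        disk = yy**2 + xx**2 <= margin_px**2
        mask = ndimage.binary_erosion(mask, structure=disk)
    if not mask.any():
        raise ApicolocError("empty tissue after erosion: margin too large")
    return mask


def _local_std(pixels: np.ndarray, window_px: int) -> np.ndarray:
    """Local standard deviation in a square window (texture energy)."""
    size = max(3, window_px | 1)  # odd window
    mean = ndimage.uniform_filter(pixels, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(pixels**2, size=size, mode="reflect")
    return np.sqrt(np.maximum(mean_sq - mean**2, 0.0))


def find_cortex(ltl: ChannelImage, muc1: ChannelImage, tissue: np.ndarray,
                texture_window_um: float = DEFAULT_TEXTURE_WINDOW_UM,
                papilla_quantile: float = DEFAULT_PAPILLA_QUANTILE,
                min_papilla_area_um2: float = DEFAULT_MIN_PAPILLA_AREA_UM2,
                ) -> np.ndarray:
    """Cortex mask: LTL-textured tissue with MUC1-bright regions removed.

    Texture energy is the local standard deviation of LTL in a
    ``texture_window_um`` window; the cortex candidate is energy above its
    Otsu-2 threshold (computed within tissue) intersected with tissue.
    Connected candidate regions whose mean MUC1 exceeds the papilla cutoff
    (``papilla_quantile`` of MUC1 within tissue) are excluded whole, so a
    MUC1-saturated papilla never contaminates the cortex.  Raises when no
    textured region exists (unusable section, to be skipped by the caller).
    """
    if not tissue.any():
        raise ApicolocError("tissue mask is empty")
    px = ltl.pixel_size_um
    energy = _local_std(ltl.pixels, int(round(texture_window_um / px)))
    try:
        # threshold over the whole energy image: textured cortex versus the
        # low-energy background and untextured tissue
        thr = threshold_otsu2(energy)
    except DegenerateInputError:
        raise ApicolocError("no LTL texture: cortex not identifiable") from None
    cand = (energy > thr) & tissue
    if not cand.any():
        raise ApicolocError("no LTL texture above threshold: empty cortex")
    # papilla: connected regions of very high MUC1 (above the papilla_quantile
    # of MUC1 within tissue) that are large enough to be anatomy rather than
    # noise speckle or apical-band fragments, padded by a small margin so the
    # texture-energy spillover at the papilla boundary is excluded with it
    cutoff = np.quantile(muc1.pixels[tissue], papilla_quantile)
    high = (muc1.pixels > cutoff) & tissue
    lab, n = ndimage.label(high, structure=EIGHT)
    if n:
        min_area_px = max(1, int(round(min_papilla_area_um2 / px**2)))
        areas = np.bincount(lab.ravel())
        small = np.flatnonzero(areas < min_area_px)
        high &= ~np.isin(lab, small[small > 0])
    if high.any():
        pad_px = max(1, int(round(2.0 / px)))
        high = ndimage.binary_dilation(high, iterations=pad_px, structure=EIGHT)
        cand = cand & ~high
        logger.info("find_cortex: excluded %d high-MUC1 (papilla-like) px",
                    int(high.sum()))
    if not cand.any():
        raise ApicolocError("cortex empty after papilla exclusion")
    return cand


def segment_apical(muc1: ChannelImage, cortex: np.ndarray,
                   high_quantile: float = DEFAULT_HIGH_QUANTILE,
                   min_speck_px: int = DEFAULT_MIN_SPECK_PX) -> np.ndarray:
    """Apical area: high-MUC1 pixels within the cortex, despeckled.

    The threshold is the ``high_quantile`` of MUC1 within cortex; connected
    components smaller than ``min_speck_px`` are removed.  Raises when no
    apical area remains (no MUC1-positive tubules).
    """
    if not 0.5 < high_quantile < 1.0:
        raise ApicolocError("high_quantile must lie in (0.5, 1)")
    thr = np.quantile(muc1.pixels[cortex], high_quantile)
    apical = (muc1.pixels >= thr) & cortex
    if min_speck_px > 1 and apical.any():
        lab, n = ndimage.label(apical, structure=EIGHT)
        areas = np.bincount(lab.ravel())
        small = np.flatnonzero(areas < min_speck_px)
        apical &= ~np.isin(lab, small[small > 0])
    if not apical.any():
        raise ApicolocError("empty apical area: no MUC1-positive tubules")
    return apical


def tubular_area(apical: np.ndarray, muc1: ChannelImage, cortex: np.ndarray,
                 low_quantile: float = DEFAULT_LOW_QUANTILE,
                 expand_um: float = DEFAULT_EXPAND_UM,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Expand the apical area by ``expand_um`` within the low-MUC1 region.

    Returns ``(muc1_low, tubular)``.  The low region is MUC1 at or above the
    ``low_quantile`` of MUC1 within cortex — cellular tissue is weakly
    MUC1-positive while the intratubular (luminal) space is not, so
    restricting the Euclidean-distance expansion to the low region excludes
    the lumen from the analysis.
    """
    if muc1.pixel_size_um <= 0:
        raise ApicolocError("pixel size required to convert the expansion distance")
    if expand_um < 0:
        raise ApicolocError("expand_um must be nonnegative")
    low_thr = np.quantile(muc1.pixels[cortex], low_quantile)
    muc1_low = muc1.pixels >= low_thr
    if expand_um == 0:
        return muc1_low, apical & muc1_low
    dist_px = ndimage.distance_transform_edt(~apical)
    reach = dist_px * muc1.pixel_size_um <= expand_um
    return muc1_low, reach & muc1_low


def build_regions(channels: dict[str, ChannelImage], *,
                  blur_sigma_um: float = 5.0, margin_um: float = 2.0,
                  texture_window_um: float = DEFAULT_TEXTURE_WINDOW_UM,
                  papilla_quantile: float = DEFAULT_PAPILLA_QUANTILE,
                  high_quantile: float = DEFAULT_HIGH_QUANTILE,
                  low_quantile: float = DEFAULT_LOW_QUANTILE,
                  expand_um: float = DEFAULT_EXPAND_UM) -> RegionSet:
    """Run the full region chain on a {DAPI, MUC1, LTL, ...} channel set."""
    dapi, muc1, ltl = channels["DAPI"], channels["MUC1"], channels["LTL"]
    tissue = segment_tissue(dapi, blur_sigma_um=blur_sigma_um, margin_um=margin_um)
    cortex = find_cortex(ltl, muc1, tissue, texture_window_um=texture_window_um,
                         papilla_quantile=papilla_quantile)
    apical = segment_apical(muc1, cortex, high_quantile=high_quantile)
    muc1_low, tubular = tubular_area(apical, muc1, cortex,
                                     low_quantile=low_quantile, expand_um=expand_um)
    regions = RegionSet(tissue=tissue, cortex=cortex, apical=apical,
                        muc1_low=muc1_low, tubular=tubular,
                        intracellular=tubular & ~apical,
                        pixel_size_um=muc1.pixel_size_um)
    regions.validate()
    return regions


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_apicality(umod: ChannelImage, regions: RegionSet,
                    positive_cutoff: float | None = None,
                    section_id: str = "") -> SectionApicality:
    """Per-tubule apicality ratios and the per-section mean.

    Tubule instances are 8-connected components of the tubular area.  Each
    tubule's mean cargo over its whole tubular area decides positivity: the
    cutoff is Otsu-2 over the per-tubule means by default (override with
    ``positive_cutoff``); when the means carry no contrast to threshold, all
    tubules are treated as positive.  For each positive tubule, A is the mean
    cargo over its apical pixels and B over its intracellular pixels; the
    ratio A/B is undefined (excluded and logged) when the intracellular area
    is empty or B == 0.  The section score is the unweighted mean ratio over
    the scored tubules; zero positive tubules is an error.
    """
    regions.validate()
    if umod.shape != regions.tubular.shape:
        raise ApicolocError("cargo channel and regions differ in shape")
    labels, n = ndimage.label(regions.tubular, structure=EIGHT)
    if n == 0:
        raise ApicolocError("no tubules: tubular area is empty")
    ids = np.arange(1, n + 1)
    px_area = regions.pixel_size_um**2
    u = umod.pixels

    mean_all = ndimage.mean(u, labels, ids)
    if positive_cutoff is None:
        # a positive/negative split needs real contrast in the per-tubule
        # means; below twofold, all tubules are cargo-positive and Otsu would
        # only split noise
        contrast = mean_all.max() / max(mean_all.min(), 1e-12)
        if contrast < 2.0:
            logger.info("score_apicality: per-tubule mean contrast %.2f < 2; "
                        "treating all %d tubules as positive", contrast, n)
            positive_cutoff = -np.inf
        else:
            try:
                positive_cutoff = threshold_otsu2(mean_all)
            except DegenerateInputError:
                positive_cutoff = -np.inf
    positive = mean_all > positive_cutoff

    ap_labels = np.where(regions.apical, labels, 0)
    in_labels = np.where(regions.intracellular, labels, 0)
    n_ap = ndimage.sum_labels(np.ones_like(u), ap_labels, ids)
    n_in = ndimage.sum_labels(np.ones_like(u), in_labels, ids)
    sum_ap = ndimage.sum_labels(u, ap_labels, ids)
    sum_in = ndimage.sum_labels(u, in_labels, ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sum_ap / n_ap
        b = sum_in / n_in
        ratio = a / b
    defined = positive & (n_ap > 0) & (n_in > 0) & (b > 0)
    ratio = np.where(defined, ratio, np.nan)

    n_excluded = int(positive.sum() - defined.sum())
    if n_excluded:
        logger.info("score_apicality: %d positive tubule(s) excluded "
                    "(empty intracellular area or B == 0)", n_excluded)
    if defined.sum() == 0:
        raise ApicolocError("no scorable cargo-positive tubules in this section")

    table = pd.DataFrame({
        "tubule": ids,
        "mean_cargo": mean_all,
        "apical_mean_A": a,
        "intracellular_mean_B": b,
        "ratio": ratio,
        "umod_positive": positive,
        "area_px": ndimage.sum_labels(np.ones_like(u), labels, ids),
        "apical_area_um2": n_ap * px_area,
        "intracellular_area_um2": n_in * px_area,
    })
    score = float(np.nanmean(ratio))
    return SectionApicality(section_id=section_id, score=score,
                            n_tubules=int(defined.sum()), tubules=table)


def score_section(channels: dict[str, ChannelImage], section_id: str = "",
                  **region_kwargs) -> tuple[SectionApicality, RegionSet]:
    """Convenience wrapper: regions then score from a 4-channel section."""
    regions = build_regions(channels, **region_kwargs)
    result = score_apicality(channels["UMOD"], regions, section_id=section_id)
    return result, regions
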