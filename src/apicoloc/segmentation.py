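"""Three-tier single-cell segmentation and marker-mask creation.

The 4i pipeline segments (1) nuclei from the DAPI channel with two-class Otsu
thresholding, (2) cells by growing each nucleus through the ER (calnexin)
foreground obtained with minimum-cross-entropy thresholding, and (3) the
cytoplasm as the per-label difference cell minus nucleus.  Objects touching
the image border are discarded before measurement.

Both thresholds operate on a 256-bin histogram of the image's intensity range
and are exhaustive over all histogram cut points, which makes them exactly
reproducible (deterministic tie-break: the lowest optimal cut).  Connected
components use 8-connectivity throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .images import (
    ApicolocError,
    BinaryMask,
    ChannelImage,
    DegenerateInputError,
    LabelMap,
    logger,
)

__all__ = [
    "threshold_otsu2",
    "threshold_min_cross_entropy",
    "segment_nuclei",
    "segment_cells",
    "derive_cytoplasm",
    "filter_border_objects",
    "marker_mask",
    "relabel_sequential",
]

N_BINS = 256
EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element

DEFAULT_MIN_NUCLEUS_AREA_PX = 50
DEFAULT_MAX_NUCLEUS_AREA_PX = 5000


# ---------------------------------------------------------------------------
# Histogram thresholds
# ---------------------------------------------------------------------------

def _histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """256-bin histogram over the image range with exact per-class sums.

    Returns bin counts, per-bin intensity sums (exact, computed from the raw
    values rather than bin centers) and the bin edges.  Using exact sums makes
    the exhaustive cut search agree with a brute-force search over raw cut
    points whenever the binning preserves the partition (always true for
    integer 8-bit data, where every value gets its own bin).
    """
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateInputError("constant image: no threshold exists")
    counts, edges = np.histogram(values, bins=N_BINS, range=(lo, hi))
    sums, _ = np.histogram(values, bins=N_BINS, range=(lo, hi), weights=values)
    return counts.astype(np.float64), sums, edges


def _cut_to_threshold(edges: np.ndarray, cut: int) -> float:
    # largest float below the first class-1 bin edge: (pixels > thr) is then
    # exactly the upper class of the histogram cut
    return float(np.nextafter(edges[cut + 1], -np.inf))


def threshold_otsu2(image: ChannelImage | np.ndarray) -> float:
    """Two-class Otsu threshold over a 256-bin histogram of the image range.

    Returns the cut value maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2``; pixels strictly above the returned value are
    foreground.  Deterministic: among equal-variance cuts the lowest is
    returned.  Raises :class:`DegenerateInputError` on constant input.
    """
    values = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    counts, sums, edges = _histogram(values.ravel())
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    sum0 = np.cumsum(sums)
    sum1 = sum0[-1] - sum0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = sum0 / w0
        mu1 = sum1 / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    between = between[:-1]  # a cut must leave both classes nonempty
    return _cut_to_threshold(edges, int(np.argmax(between)))


def threshold_min_cross_entropy(image: ChannelImage | np.ndarray) -> float:
    """Minimum cross-entropy (Li) threshold over the same 256-bin grid.

    Minimizes the Li & Lee cross-entropy criterion
    ``-(S0 * log(mu0) + S1 * log(mu1))`` where ``S`` and ``mu`` are the
    intensity sum and mean of each class, exhaustively over all histogram cut
    points.  The criterion needs positive class means, so it is defined for
    nonnegative data; cuts putting only zero-valued pixels in a class are
    skipped.
    """
    values = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    values = values.ravel().astype(np.float64)
    if values.min() < 0:
        raise DegenerateInputError(
            "minimum cross-entropy threshold requires nonnegative intensities")
    counts, sums, edges = _histogram(values)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    sum0 = np.cumsum(sums)
    sum1 = sum0[-1] - sum0
    with np.errstate(invalid="ignore", divide="ignore"):
        crit = -(sum0 * np.log(sum0 / w0) + sum1 * np.log(sum1 / w1))
    crit[~np.isfinite(crit)] = np.inf
    crit = crit[:-1]
    if not np.isfinite(crit.min()):
        raise DegenerateInputError("no valid cross-entropy cut for this image")
    return _cut_to_threshold(edges, int(np.argmin(crit)))


_THRESHOLDERS = {
    "otsu2": threshold_otsu2,
    "min_cross_entropy": threshold_min_cross_entropy,
}


def marker_mask(image: ChannelImage, method: str = "otsu2") -> BinaryMask:
    """Binary mask of above-threshold pixels for a marker channel.

    ``method`` is ``"otsu2"``, ``"min_cross_entropy"``, or ``"fixed:<value>"``
    for an absolute cutoff.  The threshold used is recorded in the mask's
    provenance.
    """
    if method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    elif method in _THRESHOLDERS:
        thr = _THRESHOLDERS[method](image)
    else:
        raise ApicolocError(f"unknown threshold method {method!r}")
    return BinaryMask(image.pixels > thr,
                      provenance=f"{image.channel}:{method}", threshold=thr)


# ---------------------------------------------------------------------------
# Label-map utilities
# ---------------------------------------------------------------------------

def relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Renumber labels contiguously from 1, preserving order."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]


# ---------------------------------------------------------------------------
# Primary / secondary / tertiary objects
# ---------------------------------------------------------------------------

def segment_nuclei(dapi: ChannelImage,
                   min_area_px: int = DEFAULT_MIN_NUCLEUS_AREA_PX,
                   max_area_px: int = DEFAULT_MAX_NUCLEUS_AREA_PX) -> LabelMap:
    """Segment nuclei from a corrected, projected DAPI image.

    Otsu-2 foreground, hole filling, distance-transform watershed to split
    touching nuclei, then removal of components outside
    ``[min_area_px, max_area_px]``.  An empty foreground yields an empty map
    with a logged warning rather than an error.
    """
    try:
        thr = threshold_otsu2(dapi)
    except DegenerateInputError:
        logger.warning("segment_nuclei: constant DAPI image; returning empty map")
        return LabelMap(np.zeros(dapi.shape, dtype=np.int32), provenance="DAPI:otsu2")
    fg = ndimage.binary_fill_holes(dapi.pixels > thr)
    if not fg.any():
        logger.warning("segment_nuclei: empty foreground; returning empty map")
        return LabelMap(np.zeros(dapi.shape, dtype=np.int32), provenance="DAPI:otsu2")

    dist = ndimage.distance_transform_edt(fg)
    # peaks at least a typical nucleus radius apart seed the watershed split
    min_dist = max(3, int(round(np.sqrt(min_area_px / np.pi))))
    peaks = peak_local_max(dist, min_distance=min_dist, labels=fg,
                           exclude_border=False)
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndimage.label(markers > 0, structure=EIGHT)
    labels = watershed(-dist, markers, mask=fg, connectivity=2)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area_px) | (areas > max_area_px))
    labels[np.isin(labels, bad[bad > 0])] = 0
    return LabelMap(relabel_sequential(labels), provenance="DAPI:otsu2+watershed")


def _propagate_labels(seeds: np.ndarray, foreground: np.ndarray) -> np.ndarray:
    """Assign each foreground pixel the label of its geodesically nearest seed.

    Multi-source BFS implemented as iterated masked 8-connected dilation: each
    sweep advances every front by one pixel, so pixels are claimed in order of
    geodesic (within-foreground) chessboard distance.  Equidistant ties go to
    the larger label id, deterministically.
    """
    labels = seeds.astype(np.int32).copy()
    free = foreground & (labels == 0)
    while free.any():
        grown = ndimage.grey_dilation(labels, footprint=EIGHT)
        newly = free & (grown > 0)
        if not newly.any():
            break  # disconnected foreground with no seed stays unlabeled
        labels[newly] = grown[newly]
        free &= ~newly
    return labels


def segment_cells(er_channel: ChannelImage, nuclei: LabelMap) -> LabelMap:
    """Secondary objects: grow each nucleus through the ER foreground.

    The foreground is the ER channel above its minimum-cross-entropy
    threshold, unioned with the nuclei; every foreground pixel is assigned to
    the geodesically nearest seed nucleus, so each cell contains its nucleus
    and cells partition connected blobs along geodesic midlines.
    """
    if er_channel.shape != nuclei.shape:
        raise ApicolocError("ER channel and nuclei differ in shape")
    if nuclei.n_objects == 0:
        return LabelMap(np.zeros(nuclei.shape, dtype=np.int32),
                        provenance="cells:no-seeds")
    try:
        thr = threshold_min_cross_entropy(er_channel)
        fg = er_channel.pixels > thr
    except DegenerateInputError:
        fg = np.zeros(er_channel.shape, dtype=bool)
    fg |= nuclei.labels > 0
    labels = _propagate_labels(nuclei.labels, fg)
    return LabelMap(labels, provenance=f"cells:{er_channel.channel}:min_cross_entropy")


def derive_cytoplasm(cells: LabelMap, nuclei: LabelMap) -> LabelMap:
    """Tertiary objects: per-label set difference of cell minus nucleus.

    Raises when any nucleus pixel falls outside its own cell (inconsistent
    segmentation); a cell that equals its nucleus gets an empty cytoplasm.
    """
    if cells.shape != nuclei.shape:
        raise ApicolocError("cells and nuclei differ in shape")
    nuc = nuclei.labels
    inside = nuc > 0
    if np.any(cells.labels[inside] != nuc[inside]):
        raise ApicolocError("inconsistent segmentation: nucleus pixel outside its cell")
    cyto = cells.labels.copy()
    cyto[inside] = 0
    return LabelMap(cyto, provenance="cytoplasm:cells-minus-nuclei")


def filter_border_objects(labels: LabelMap) -> LabelMap:
    """Remove every object owning at least one pixel on the image border."""
    arr = labels.labels
    border_ids = np.unique(np.concatenate([
        arr[0, :], arr[-1, :], arr[:, 0], arr[:, -1]]))
    border_ids = border_ids[border_ids > 0]
    out = arr.copy()
    if border_ids.size:
        out[np.isin(out, border_ids)] = 0
    return LabelMap(relabel_sequential(out),
                    provenance=labels.provenance + "+border-filtered")
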