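"""End-to-end 4i well analysis: stack in, per-cell colocalization table out.

Glues the stages together in acquisition order: projection, cross-cycle
alignment on DAPI, flat-field correction, three-tier segmentation (nuclei
from cycle-1 DAPI, cells from the ER channel, border filtering), marker
masks, and the per-cell Pearson / compartment-overlap measurements.
"""

from __future__ import annotations

import pandas as pd
from scipy import ndimage

from .colocalization import cell_table, overlap_fraction, pearson_per_cell
from .images import DAPI, CycleStack
from .registration import align_and_crop, estimate_illumination, flatfield_correct
from .segmentation import (
    filter_border_objects,
    marker_mask,
    segment_cells,
    segment_nuclei,
)

__all__ = ["analyze_4i_well"]


def analyze_4i_well(stack: CycleStack, *, er_channel: str = "CANX",
                    cargo_channel: str = "UMOD",
                    compartment_channels: tuple[str, ...] = (),
                    pearson_pairs: tuple[tuple[str, str], ...] = (),
                    mask_method: str = "otsu2",
                    max_shift_px: int = 32,
                    flatfield: bool = False,
                    min_nucleus_area_px: int = 50,
                    max_nucleus_area_px: int = 5000,
                    well: str = "") -> pd.DataFrame:
    """Run the full single-cell 4i analysis on one well's stack.

    Returns a tidy per-cell table with the compartment-overlap fraction of the
    cargo marker for every compartment channel and the Pearson correlation for
    every requested marker pair.  ``flatfield`` enables illumination
    correction estimated from the aligned images themselves (useful for real
    acquisitions with vignetting; synthetic flat fields do not need it).
    """
    aligned, _shifts = align_and_crop(stack, max_shift_px=max_shift_px)
    images = {im.channel: im for im in aligned.iter_images()}
    images[DAPI] = aligned.get(1, DAPI)  # nuclei always from cycle-1 DAPI
    if flatfield:
        for name, im in images.items():
            surface = estimate_illumination([im])
            images[name] = flatfield_correct(im, surface)

    nuclei = segment_nuclei(images[DAPI], min_area_px=min_nucleus_area_px,
                            max_area_px=max_nucleus_area_px)
    cells = filter_border_objects(segment_cells(images[er_channel], nuclei))

    cargo = marker_mask(images[cargo_channel], method=mask_method)
    metrics: dict[str, pd.Series] = {}
    for comp in compartment_channels:
        comp_mask = marker_mask(images[comp], method=mask_method)
        metrics[f"overlap_{cargo_channel}_{comp}"] = overlap_fraction(
            cargo, comp_mask, cells)
    for a, b in pearson_pairs:
        metrics[f"pearson_{a}_{b}"] = pearson_per_cell(images[a], images[b], cells)
    # per-marker mean intensity per cell, always reported
    ids = cells.ids()
    for name, im in images.items():
        if name == DAPI:
            continue
        means = ndimage.mean(im.pixels, cells.labels, ids) if ids.size else []
        metrics[f"mean_{name}"] = pd.Series(means, index=pd.Index(ids, name="cell"))
    return cell_table(metrics, well=well)
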