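"""Per-cell colocalization statistics and the treatment-vs-control delta.

For every segmented cell the pipeline computes the sample Pearson correlation
between marker pairs over that cell's pixels, and the proportion of the cargo
marker's mask overlapping each subcellular compartment mask.  Cell values are
averaged per well; each treated well's mean is compared against the control
mean and the per-replicate deltas are tested against zero with a one-sample
two-tailed t-test.

Cells in which a marker is constant have an undefined correlation; cells with
no cargo pixels have undefined overlap fractions.  Undefined values propagate
as NaN, are excluded from well means, and the exclusion count is logged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import (
    ApicolocError,
    BinaryMask,
    ChannelImage,
    InconsistentStackError,
    LabelMap,
    logger,
)
from .stats_report import one_sample_t

__all__ = [
    "pearson_per_cell",
    "overlap_fraction",
    "cell_table",
    "summarize_wells",
    "treatment_delta",
]


def _check_shapes(*shapes: tuple[int, int]) -> None:
    if len(set(shapes)) > 1:
        raise InconsistentStackError(f"inputs are not aligned: shapes {set(shapes)}")


def pearson_per_cell(img_a: ChannelImage, img_b: ChannelImage,
                     cells: LabelMap) -> pd.Series:
    """Sample Pearson correlation of two markers within each cell.

    Returns a Series indexed by cell id; NaN where either marker has zero
    variance within the cell (undefined correlation, excluded from
    aggregates).
    """
    _check_shapes(img_a.shape, img_b.shape, cells.shape)
    ids = cells.ids()
    if ids.size == 0:
        return pd.Series(dtype=float, name="pearson_r")
    a, b, lab = img_a.pixels, img_b.pixels, cells.labels
    n = ndimage.sum_labels(np.ones_like(a), lab, ids)
    s_a = ndimage.sum_labels(a, lab, ids)
    s_b = ndimage.sum_labels(b, lab, ids)
    s_aa = ndimage.sum_labels(a * a, lab, ids)
    s_bb = ndimage.sum_labels(b * b, lab, ids)
    s_ab = ndimage.sum_labels(a * b, lab, ids)
    cov = s_ab - s_a * s_b / n
    var_a = s_aa - s_a**2 / n
    var_b = s_bb - s_b**2 / n
    # guard: zero variance within a cell -> undefined r (scale-aware cutoff)
    tol_a = 1e-12 * np.maximum(s_aa, 1.0)
    tol_b = 1e-12 * np.maximum(s_bb, 1.0)
    ok = (n >= 2) & (var_a > tol_a) & (var_b > tol_b)
    r = np.full(ids.shape, np.nan)
    r[ok] = cov[ok] / np.sqrt(var_a[ok] * var_b[ok])
    n_undef = int((~ok).sum())
    if n_undef:
        logger.info("pearson_per_cell(%s, %s): %d of %d cells undefined",
                    img_a.channel, img_b.channel, n_undef, ids.size)
    return pd.Series(r, index=pd.Index(ids, name="cell"), name="pearson_r")


def overlap_fraction(cargo_mask: BinaryMask, compartment_mask: BinaryMask,
                     cells: LabelMap) -> pd.Series:
    """Per-cell proportion of cargo pixels falling inside a compartment.

    For each cell: ``|cargo & compartment & cell| / |cargo & cell|``; NaN for
    cells with no cargo pixels (undefined, excluded from aggregates).
    """
    _check_shapes(cargo_mask.shape, compartment_mask.shape, cells.shape)
    ids = cells.ids()
    if ids.size == 0:
        return pd.Series(dtype=float, name="overlap_fraction")
    lab = cells.labels
    cargo = cargo_mask.mask.astype(np.float64)
    both = (cargo_mask.mask & compartment_mask.mask).astype(np.float64)
    n_cargo = ndimage.sum_labels(cargo, lab, ids)
    n_both = ndimage.sum_labels(both, lab, ids)
    frac = np.full(ids.shape, np.nan)
    ok = n_cargo > 0
    frac[ok] = n_both[ok] / n_cargo[ok]
    n_undef = int((~ok).sum())
    if n_undef:
        logger.info("overlap_fraction: %d of %d cells have no cargo", n_undef, ids.size)
    return pd.Series(frac, index=pd.Index(ids, name="cell"), name="overlap_fraction")


def cell_table(metrics: dict[str, pd.Series], well: str = "",
               field_id: str = "") -> pd.DataFrame:
    """Assemble per-cell metric Series into one tidy CellRecord table."""
    df = pd.DataFrame(metrics)
    df.insert(0, "well", well)
    df.insert(1, "field", field_id)
    return df


def summarize_wells(cell_tables: pd.DataFrame,
                    treatment_by_well: dict[str, str] | None = None) -> pd.DataFrame:
    """Well-level summary: per-metric mean over all cells of the well.

    NaN (undefined) cell values are excluded metric-by-metric; ``n_cells``
    counts all cells in the well.
    """
    metric_cols = [c for c in cell_tables.columns if c not in ("well", "field")]
    grouped = cell_tables.groupby("well")
    out = grouped[metric_cols].mean()
    out["n_cells"] = grouped.size()
    if (out["n_cells"] < 1).any():
        raise ApicolocError("a well summary requires at least one cell")
    if treatment_by_well is not None:
        out.insert(0, "treatment", out.index.map(treatment_by_well))
    return out.reset_index()


@dataclass
class TreatmentDelta:
    """Per-replicate treated-minus-control deltas with the one-sample test."""

    metric: str
    deltas: np.ndarray
    t: float
    p: float
    df: int


def treatment_delta(wells: pd.DataFrame, treated_label: str, control_label: str,
                    metric: str, design: str = "pooled") -> TreatmentDelta:
    """Change induced by treatment, per replicate, tested against zero.

    ``design="pooled"`` (default): each treated well's mean minus the mean of
    all control wells.  ``design="paired"``: treated and control wells are
    matched by their order within each treatment group (per-plate pairing).
    The deltas are tested with a two-tailed one-sample t-test against a
    theoretical mean of 0.
    """
    treated = wells[wells["treatment"] == treated_label]
    control = wells[wells["treatment"] == control_label]
    if len(treated) < 2:
        raise ApicolocError("need >= 2 treated replicates for a t-test")
    if len(control) < 1:
        raise ApicolocError("need >= 1 control replicate")
    tvals = treated[metric].to_numpy(dtype=float)
    cvals = control[metric].to_numpy(dtype=float)
    if design == "pooled":
        deltas = tvals - np.nanmean(cvals)
    elif design == "paired":
        if len(tvals) != len(cvals):
            raise ApicolocError("paired design requires equal group sizes")
        deltas = tvals - cvals
    else:
        raise ApicolocError(f"unknown design {design!r}")
    t, p, df = one_sample_t(deltas, mu0=0.0)
    return TreatmentDelta(metric=metric, deltas=deltas, t=t, p=p, df=df)
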