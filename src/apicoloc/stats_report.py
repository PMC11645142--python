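"""Replicate-level aggregation and closed-form t-tests, tables and plots.

Object- or field-level measurements are averaged to one value per replicate
unit (well, animal, or section) per metric, and group comparisons use the
closed-form Student statistics: a two-tailed one-sample t-test against a
theoretical mean, and Welch's unequal-variance two-sample t-test.  Only the
tail probabilities come from scipy's Student-t distribution; the statistics
themselves are computed from the textbook formulas.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .images import ApicolocError, DegenerateInputError, logger

__all__ = [
    "GroupDesign",
    "aggregate",
    "one_sample_t",
    "two_sample_t",
    "plot_histogram",
    "run_manifest",
]


@dataclass
class GroupDesign:
    """Replication design: what the unit of replication is and how units map
    to groups (e.g. genotype x treatment), with an optional pairing scheme."""

    unit: str = "well"  # "well" | "animal" | "section"
    group_col: str = "treatment"
    pairing: str | None = None

    def validate(self, records: pd.DataFrame) -> None:
        for col in (self.unit, self.group_col):
            if col not in records.columns:
                raise ApicolocError(f"records lack required column {col!r}")
        groups_per_unit = records.groupby(self.unit)[self.group_col].nunique()
        if (groups_per_unit > 1).any():
            bad = groups_per_unit[groups_per_unit > 1].index.tolist()
            raise ApicolocError(f"replicate units in multiple groups: {bad}")


def aggregate(records: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Mean per replicate unit per metric, with n and missing-exclusion counts.

    Metric columns are every numeric column other than the design columns.
    NaN observations are excluded from the means; a unit without a single
    usable observation for some metric gets a flagged row (``flagged=True``).
    """
    if len(records) == 0:
        raise ApicolocError("no records to aggregate")
    design.validate(records)
    metric_cols = [c for c in records.columns
                   if c not in (design.unit, design.group_col)
                   and pd.api.types.is_numeric_dtype(records[c])]
    g = records.groupby(design.unit)
    out = g[metric_cols].mean()
    out["n_obs"] = g.size()
    for c in metric_cols:
        out[f"n_missing_{c}"] = g[c].apply(lambda s: int(s.isna().sum()))
    out["flagged"] = out[metric_cols].isna().any(axis=1)
    if out["flagged"].any():
        logger.warning("aggregate: %d replicate unit(s) flagged with no usable "
                       "observations for some metric", int(out["flagged"].sum()))
    groups = records.groupby(design.unit)[design.group_col].first()
    out.insert(0, design.group_col, groups)
    return out.reset_index()


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float, int]:
    """Two-tailed one-sample t-test: ``t = (mean - mu0) / (sd / sqrt(n))``.

    ``sd`` is the n-1 sample standard deviation; the p-value comes from
    Student's t with ``df = n - 1``.  Raises on n < 2 or zero variance
    (degenerate; reported as such rather than an invented p).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ApicolocError("one-sample t-test needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("degenerate variance: all values identical")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    p = 2.0 * _scipy_stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), n - 1


def two_sample_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unpaired two-tailed t-test (unequal variances).

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with the
    Welch-Satterthwaite degrees of freedom.  Raises when both groups have zero
    variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ApicolocError("Welch t-test needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateInputError("degenerate variance in both groups")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    p = 2.0 * _scipy_stats.t.sf(abs(t), df=df)
    return float(t), float(p), float(df)


def plot_histogram(values, title: str, path, bins: int = 50,
                   xlabel: str = "single-cell Pearson r") -> None:
    """Histogram of single-cell statistics (e.g. per-cell correlation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(vals, bins=bins, color="#4878d0")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cells")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_manifest(config: dict, seeds: dict | None = None) -> dict:
    """Reproducibility manifest: config hash, seeds, library versions."""
    import matplotlib
    import scipy
    import skimage

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": seeds or {},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
            "matplotlib": matplotlib.__version__,
        },
    }
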