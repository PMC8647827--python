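"""Expression-outlier calling.

Expression is Z-transformed per gene within each tissue (sample standard
deviation, n-1 denominator).  Gene/sample pairs with data in at least five
tissues are then classified, each rule applied independently:

* multitissue       |median Z across available tissues| >= 2
* tissue_restricted |Z| >= 4 in at least two tissues ("primary" outliers)
* secondary         |Z| >= 3 in at least two tissues
* control           |Z| < 1 in every available tissue

Samples with grossly excessive outlier counts (above Q3 + 3 IQR of the
per-sample counts) can be flagged and removed, mirroring cohort-level
quality exclusions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genio import ExpressionPanel

__all__ = [
    "zscore_panel",
    "call_outliers",
    "flag_excess_outlier_samples",
    "OUTLIER_CLASSES",
]

OUTLIER_CLASSES = ("multitissue", "tissue_restricted", "secondary", "control")


def zscore_panel(panel: ExpressionPanel) -> pd.DataFrame:
    """Per-gene Z-scores across samples within a tissue; genes with zero
    variance (or < 2 observations) get all-missing Z."""
    vals = panel.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    n_obs = np.sum(~np.isnan(vals), axis=1, keepdims=True)
    z = (vals - mean) / sd
    z[np.broadcast_to((sd == 0) | (n_obs < 2), z.shape)] = np.nan
    return pd.DataFrame(z, index=panel.values.index, columns=panel.values.columns)


def call_outliers(
    z_by_tissue: dict[str, pd.DataFrame],
    min_tissues: int = 5,
    multitissue_threshold: float = 2.0,
    primary_threshold: float = 4.0,
    secondary_threshold: float = 3.0,
    control_threshold: float = 1.0,
    min_tissues_hit: int = 2,
    samples_keep: list[str] | None = None,
) -> pd.DataFrame:
    """Classify every gene/sample pair with Z-scores in >= ``min_tissues``
    tissues.  Returns one row per usable pair with independent boolean class
    columns (a pair may satisfy several outlier rules; it can never be both
    control and an outlier class), the median Z and tissue count.
    ``samples_keep`` restricts the sample universe (e.g. one ancestry group).
    """
    tissues = sorted(z_by_tissue)
    first = z_by_tissue[tissues[0]]
    genes = first.index
    samples = pd.Index(samples_keep) if samples_keep is not None else first.columns
    cube = np.stack(
        [z_by_tissue[t].reindex(index=genes, columns=samples).to_numpy(dtype=float)
         for t in tissues],
        axis=2,
    )  # genes x samples x tissues
    n_avail = np.sum(~np.isnan(cube), axis=2)
    absz = np.abs(cube)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(cube, axis=2)
    multitissue = np.abs(med) >= multitissue_threshold
    primary = np.nansum(absz >= primary_threshold, axis=2) >= min_tissues_hit
    secondary = np.nansum(absz >= secondary_threshold, axis=2) >= min_tissues_hit
    control = np.all(np.where(np.isnan(absz), True, absz < control_threshold), axis=2) & (
        n_avail > 0
    )
    usable = n_avail >= min_tissues
    gi, si = np.nonzero(usable)
    return pd.DataFrame(
        {
            "gene_id": genes.to_numpy()[gi],
            "sample_id": samples.to_numpy()[si],
            "n_tissues_available": n_avail[gi, si],
            "median_z": med[gi, si],
            "multitissue": multitissue[gi, si],
            "tissue_restricted": primary[gi, si],
            "secondary": secondary[gi, si],
            "control": control[gi, si],
        }
    )


def flag_excess_outlier_samples(
    calls: pd.DataFrame,
    classes: tuple[str, ...] = ("multitissue", "tissue_restricted"),
) -> list[str]:
    """Samples whose outlier count exceeds Q3 + 3 IQR of the per-sample
    counts (cohort-level quality exclusion; returns the excluded ids)."""
    is_outlier = calls[list(classes)].any(axis=1)
    counts = (
        calls.loc[is_outlier].groupby("sample_id").size()
        .reindex(calls["sample_id"].unique(), fill_value=0)
    )
    q1, q3 = np.percentile(counts, [25, 75])
    threshold = q3 + 3 * (q3 - q1)
    return sorted(counts.index[counts > threshold])
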