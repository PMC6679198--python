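"""Median-of-ratios count normalization.

Raw RNA-seq read counts are not comparable across samples because sequencing
depth and library composition differ.  The classic size-factor remedy: build a
pseudo-reference sample as the per-gene geometric mean across samples, and set
each sample's size factor to the median, over reference genes, of the ratio
count / reference.  Dividing a sample's counts by its size factor puts all
samples on a common scale.  Genes with a zero count in any sample are excluded
from the reference set (their geometric mean is degenerate); an optional
``poscounts``-style fallback handles zero-heavy matrices by taking the
geometric mean over positive samples only.

No variance-stabilizing transform or dispersion modelling is done here — the
downstream screen is rank-based, so scaling alone suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["NormalizedMatrix", "estimate_size_factors", "normalize_counts"]


@dataclass
class NormalizedMatrix:
    """Normalized expression values (genes x samples) with their size factors."""

    values: pd.DataFrame
    size_factors: pd.Series

    @property
    def gene_symbols(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def estimate_size_factors(counts: pd.DataFrame, poscounts: bool = False) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    Parameters
    ----------
    counts
        Genes x samples matrix of non-negative raw counts.
    poscounts
        If True, compute each gene's geometric mean over its *positive*
        samples only and take the per-sample median of ratios over genes with
        a positive count in that sample.  Use for zero-heavy matrices where no
        gene is positive everywhere.

    Raises
    ------
    ValueError
        If no gene has all-positive counts (and `poscounts` is False), or
        counts are negative.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene symbols or sample ids")

    with np.errstate(divide="ignore"):
        logx = np.log(x)

    if not poscounts:
        all_pos = np.all(x > 0, axis=1)
        if not all_pos.any():
            raise ValueError(
                "no gene has positive counts in every sample; "
                "re-run with poscounts=True (pseudo-reference fallback)"
            )
        log_ref = logx[all_pos].mean(axis=1)  # log geometric mean per gene
        log_ratios = logx[all_pos] - log_ref[:, None]
        log_sf = np.median(log_ratios, axis=0)
    else:
        pos = x > 0
        n_pos = pos.sum(axis=1)
        usable = n_pos > 0
        log_ref = np.full(x.shape[0], np.nan)
        log_ref[usable] = np.where(pos[usable], logx[usable], 0.0).sum(axis=1) / n_pos[usable]
        log_ratios = np.where(pos, logx - log_ref[:, None], np.nan)
        log_sf = np.nanmedian(log_ratios[usable], axis=0)

    sf = np.exp(log_sf)
    if not np.all(np.isfinite(sf)) or (sf <= 0).any():
        raise ValueError("degenerate size factors; check the count matrix")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series | None = None,
                     poscounts: bool = False) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor.

    If `size_factors` is omitted they are estimated from `counts`.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts, poscounts=poscounts)
    sf = pd.Series(size_factors)
    if len(sf) != counts.shape[1]:
        raise ValueError(
            f"{len(sf)} size factors for {counts.shape[1]} samples"
        )
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    if not sf.index.equals(counts.columns):
        sf = sf.reindex(counts.columns)
        if sf.isna().any():
            raise ValueError("size factor index does not match sample ids")
    values = counts.astype(float).div(sf, axis=1)
    return NormalizedMatrix(values=values, size_factors=sf)
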