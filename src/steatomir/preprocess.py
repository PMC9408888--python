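"""Count-table clean-up and normalization.

Three clean-up rules mirror the biomarker-discovery workflow for paired
liver/serum small-RNA cohorts:

1. per-tissue detection filter -- a miRNA must be detected (raw count >= 1)
   in at least ``ceil(min_fraction * n_samples)`` samples;
2. cross-matrix median filter -- miRNAs whose median raw count is strictly
   higher in serum than in liver are removed (serum-dominant species are
   unlikely to be hepatically released);
3. median-of-ratios size-factor normalization, applied per tissue matrix
   after filtering.

The detection threshold uses ceiling arithmetic, so 90% of 20 samples means
"at least 18" and 82.5% of 23 samples means "at least 19".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import CountMatrix, NormalizedMatrix, ValidationError

__all__ = [
    "compute_size_factors",
    "normalize",
    "detection_filter",
    "cross_matrix_median_filter",
    "common_feature_set",
]


def compute_size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    For every miRNA with strictly positive counts in *all* samples, form the
    ratio of each sample's count to the row geometric mean; the size factor
    of a sample is the median of those ratios.  Rows containing any zero are
    excluded from the reference set.  Factors are not rescaled afterward.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError("no all-positive features for size-factor reference")
    ref = counts[all_positive]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def normalize(m: CountMatrix) -> NormalizedMatrix:
    """Divide each sample column by its median-of-ratios size factor."""
    factors = compute_size_factors(m)
    values = m.counts / factors
    return NormalizedMatrix(values, factors)


def detection_filter(m: CountMatrix, min_fraction: float) -> list[str]:
    """IDs of miRNAs detected (count >= 1) in at least ceil(min_fraction * n) samples."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValidationError(f"min_fraction must be in [0, 1], got {min_fraction}")
    n = m.counts.shape[1]
    required = int(np.ceil(min_fraction * n))
    detected = (m.counts >= 1).sum(axis=1)
    keep = detected >= required
    return [mid for mid, k in zip(m.mirna_ids, keep) if k]


def cross_matrix_median_filter(liver: CountMatrix, serum: CountMatrix) -> list[str]:
    """Drop miRNAs whose median raw count is strictly higher in serum than in liver.

    Operates on the intersection of the two ID sets (liver order); equal
    medians are retained.
    """
    common = [mid for mid in liver.mirna_ids if mid in set(serum.mirna_ids)]
    if not common:
        raise ValidationError("liver and serum matrices share no miRNA IDs")
    liver_med = liver.counts.loc[common].median(axis=1)
    serum_med = serum.counts.loc[common].median(axis=1)
    return [mid for mid in common if serum_med[mid] <= liver_med[mid]]


def common_feature_set(
    liver: CountMatrix,
    serum: CountMatrix,
    liver_frac: float = 0.90,
    serum_frac: float = 0.825,
) -> list[str]:
    """Joint clean-up: per-tissue detection filters, then the cross-matrix median filter.

    Returns the retained IDs in liver-matrix order.
    """
    liver_keep = set(detection_filter(liver, liver_frac))
    serum_keep = set(detection_filter(serum, serum_frac))
    both = [mid for mid in liver.mirna_ids if mid in liver_keep and mid in serum_keep]
    if not both:
        return []
    liver_sub = liver.subset(both)
    serum_sub = serum.subset(both)
    return cross_matrix_median_filter(liver_sub, serum_sub)
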