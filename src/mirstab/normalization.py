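"""Median-of-ratios size-factor normalization and expression filters.

The size factor of a sample is the median, over reference features, of the
ratio between that sample's count and the feature's geometric mean across
all samples.  Reference features are those with strictly positive counts in
every sample, so the geometric mean is well defined.  Dividing each column
by its factor yields normalized counts comparable across samples; each
dataset (the healthy time course and every cancer study) is normalized
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Feature × sample table of size-factor-normalized counts."""

    values: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be strictly positive")

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Raises
    ------
    ValueError
        If no feature has strictly positive counts in all samples (the
        reference set is empty); filter features or samples first.
    """
    counts = cm.counts.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "the median-of-ratios reference set is empty — filter low-count "
            "features or drop empty samples first"
        )
    log_ref = np.log(counts[ref])
    log_geomean = log_ref.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ref - log_geomean, axis=0))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def normalize(cm: CountMatrix) -> NormalizedMatrix:
    """Divide each sample column by its median-of-ratios size factor."""
    factors = size_factors(cm)
    values = cm.counts.astype(float).div(factors, axis=1)
    return NormalizedMatrix(values=values, size_factors=factors)


def filter_low_expression(nm: NormalizedMatrix, min_mean: float) -> NormalizedMatrix:
    """Drop features whose mean normalized count is below ``min_mean``.

    Features with mean strictly under the threshold are discarded (a mean
    of exactly ``min_mean`` is kept); the discarded ids are logged.
    """
    if not min_mean > 0:
        raise ValueError("min_mean must be positive")
    keep = nm.values.mean(axis=1) >= min_mean
    dropped = nm.values.index[~keep].tolist()
    if dropped:
        logger.info(
            "filter_low_expression: discarded %d/%d features below mean %g: %s",
            len(dropped), len(keep), min_mean,
            dropped if len(dropped) <= 20 else dropped[:20] + ["..."],
        )
    return NormalizedMatrix(values=nm.values.loc[keep], size_factors=nm.size_factors)


def common_features(nm: NormalizedMatrix, st: SampleTable, min_mean: float) -> set[str]:
    """Features expressed at every time point of a healthy time course.

    A feature qualifies when its mean normalized count within *every*
    time-point group is at least ``min_mean``.
    """
    if not min_mean > 0:
        raise ValueError("min_mean must be positive")
    timepoints = st.timepoints_h
    if not timepoints:
        raise ValueError("sample table has no time points")
    keep = pd.Series(True, index=nm.values.index)
    for t in timepoints:
        samples = st.samples_at(t)
        if not samples:
            raise ValueError(f"time point {t} h has no samples")
        keep &= nm.values[samples].mean(axis=1) >= min_mean
    return set(nm.values.index[keep])
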