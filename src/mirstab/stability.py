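"""Temporal-stability scoring of healthy time-course miRNA expression.

Step 1 of the panel-discovery procedure.  For each miRNA, the expression
at every time point is compared to its overall mean across all samples as
a log2 fold change, giving an ordered vector ``X`` of one value per time
point.  Robust variability is then summarized by the median absolute
deviation

    MAD(X) = b * median(|X - median(X)|),        b = 1.4826,

where ``b`` makes the MAD a consistent estimator of the standard deviation
under normality.  A miRNA is *stable* when MAD < 0.2 (log2 units), and its
healthy reference window is ``median(X) ± k·MAD`` with ``k = 3``: cancer
fold changes falling outside this window later count as outliers.

Two confirmatory analyses accompany the score: agglomerative clustering of
the temporal profiles (the cluster with the lowest mean MAD plays the role
of the "stable cluster"), and a single-component cosinor fit testing each
profile for residual rhythmicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .config import PipelineConfig
from .io import SampleTable
from .normalization import NormalizedMatrix


def timepoint_log2fc(
    nm: NormalizedMatrix,
    st: SampleTable,
    pseudocount: float = 1.0,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Per-feature log2 fold change of each time point vs the overall mean.

    ``X_t = log2((mean over samples at t + pc) / (mean over all samples + pc))``.

    Returns a feature × time-point DataFrame with columns ordered by
    ascending time (hours).  With ``per_sample=True`` every sample
    contributes its own column ``log2((value + pc) / (overall mean + pc))``
    instead of the time-point average.
    """
    timepoints = st.timepoints_h
    if len(timepoints) < 2:
        raise ValueError("need at least two time points")
    samples = [s for t in timepoints for s in st.samples_at(t)]
    values = nm.values[samples]
    overall = values.mean(axis=1)
    if per_sample:
        cols = {s: np.log2((values[s] + pseudocount) / (overall + pseudocount))
                for s in samples}
        return pd.DataFrame(cols, index=values.index)
    out = {}
    for t in timepoints:
        group = st.samples_at(t)
        if not group:
            raise ValueError(f"time point {t} h has no samples")
        gmean = values[group].mean(axis=1)
        out[t] = np.log2((gmean + pseudocount) / (overall + pseudocount))
    return pd.DataFrame(out, index=values.index)


def mad_score(x: np.ndarray | list[float], b: float = 1.4826) -> float:
    """Scaled median absolute deviation ``b * median(|x - median(x)|)``.

    Even-length medians use the midpoint of the two central order
    statistics, so the score is reproducible bit for bit.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("mad_score of an empty vector")
    med = np.median(arr)
    return float(b * np.median(np.abs(arr - med)))


def threshold_window(
    x: np.ndarray | list[float], b: float = 1.4826, k: float = 3.0
) -> tuple[float, float]:
    """Stability window ``median(x) ± k·MAD(x)`` as ``(lower, upper)``."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("threshold_window of an empty vector")
    med = float(np.median(arr))
    half = k * mad_score(arr, b)
    return med - half, med + half


def select_stable(mad_by_feature: pd.Series, mad_cutoff: float = 0.2) -> set[str]:
    """Feature ids with MAD strictly below the cutoff."""
    return set(mad_by_feature.index[mad_by_feature < mad_cutoff])


def cluster_profiles(
    x_matrix: pd.DataFrame, k: int, seed: int | None = None
) -> pd.Series:
    """Partition temporal profiles into ``k`` groups.

    Deterministic agglomerative clustering: Euclidean distance on the X
    vectors, Ward linkage, tree cut at ``k`` clusters.  Identical
    profiles always share a label; if ties collapse the tree below ``k``
    distinct groups the remaining labels are simply unused.  ``seed`` is
    accepted for interface symmetry but unused — the method has no
    stochastic step.

    Labels are integers ``0..k-1`` renumbered by first appearance in the
    input row order.
    """
    n = len(x_matrix)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    z = linkage(x_matrix.to_numpy(), method="ward", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        labels[i] = relabel.setdefault(lab, len(relabel))
    return pd.Series(labels, index=x_matrix.index, name="cluster")


def stable_cluster(labels: pd.Series, mad_by_feature: pd.Series) -> int:
    """Label of the cluster with the lowest mean MAD (the stable cluster)."""
    return int(mad_by_feature.groupby(labels).mean().idxmin())


@dataclass
class CosinorFit:
    """Least-squares single-component cosinor fit.

    ``y = mesor + amplitude * cos(2π (t − acrophase_h) / period_h)``;
    ``p_amplitude`` is the F-test p-value of zero amplitude.
    """

    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    p_amplitude: float


def cosinor_fit(
    y: np.ndarray | list[float],
    times_h: np.ndarray | list[float],
    period_h: float = 24.0,
) -> CosinorFit:
    """Fit a cosine of known period by linear least squares.

    Uses the linear parameterization
    ``y = M + β cos(2πt/τ) + γ sin(2πt/τ)`` with ``A = sqrt(β² + γ²)`` and
    acrophase from ``atan2(γ, β)``; the zero-amplitude test is the F-test
    of ``β = γ = 0`` against the intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if y.shape != t.shape:
        raise ValueError("y and times_h must have equal length")
    n = y.size
    if n < 4:
        raise ValueError("cosinor fit needs at least 4 observations")
    w = 2 * np.pi * t / period_h
    design = np.column_stack([np.ones(n), np.cos(w), np.sin(w)])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise ValueError("degenerate cosinor design (times alias the period)")
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    acrophase = float((np.arctan2(gamma, beta) * period_h / (2 * np.pi)) % period_h)
    rss_full = float(np.sum((y - design @ coef) ** 2))
    rss_null = float(np.sum((y - y.mean()) ** 2))
    df_den = n - 3
    if rss_full <= 1e-30 * max(rss_null, 1.0):
        # perfect fit: rhythmic iff the harmonic explains anything at all
        p = 0.0 if rss_null > 1e-30 else 1.0
    else:
        f = ((rss_null - rss_full) / 2) / (rss_full / df_den)
        p = float(stats.f.sf(f, 2, df_den))
    return CosinorFit(float(mesor), amplitude, acrophase, float(period_h), p)


@dataclass
class StabilityProfile:
    """Full stability record for a single miRNA."""

    feature_id: str
    log2fc_by_timepoint: pd.Series
    median_fc: float
    mad: float
    window_lower: float
    window_upper: float
    stable: bool
    cluster: int
    cosinor: CosinorFit


def stability_table(
    nm: NormalizedMatrix,
    st: SampleTable,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Compute the per-miRNA stability report for a healthy time course.

    Returns one row per feature with the time-point log2FC columns
    (``X_<t>h``), ``median_fc``, ``mad``, ``lower``/``upper`` window
    borders, the boolean ``stable`` call, a temporal ``cluster`` label and
    cosinor ``cosinor_amplitude``/``cosinor_p``.
    """
    cfg = config or PipelineConfig()
    x = timepoint_log2fc(nm, st, cfg.pseudocount)
    timepoints = list(x.columns)
    arr = x.to_numpy()
    med = np.median(arr, axis=1)
    mad = cfg.mad_b * np.median(np.abs(arr - med[:, None]), axis=1)
    lower = med - cfg.window_k * mad
    upper = med + cfg.window_k * mad

    k = min(cfg.n_clusters, max(2, len(x)))
    if len(x) >= 2 and k >= 2:
        clusters = cluster_profiles(x, k, cfg.rng_seed)
    else:
        clusters = pd.Series(0, index=x.index)

    fit_t = [t for t in timepoints if t <= cfg.cosinor_max_time_h]
    if len(fit_t) < 4:
        fit_t = timepoints
    amp = np.empty(len(x))
    pcos = np.empty(len(x))
    for i, fid in enumerate(x.index):
        fit = cosinor_fit(x.loc[fid, fit_t].to_numpy(), fit_t, cfg.cosinor_period_h)
        amp[i] = fit.amplitude
        pcos[i] = fit.p_amplitude

    out = x.copy()
    out.columns = [f"X_{t:g}h" for t in timepoints]
    out["median_fc"] = med
    out["mad"] = mad
    out["lower"] = lower
    out["upper"] = upper
    out["stable"] = mad < cfg.mad_cutoff
    out["cluster"] = clusters
    out["cosinor_amplitude"] = amp
    out["cosinor_p"] = pcos
    out.index.name = "feature_id"
    return out
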