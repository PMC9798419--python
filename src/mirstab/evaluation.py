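"""Diagnostic-performance summaries: ROC/AUC, panel combiner, PCA variance.

The AUC is computed through the Mann–Whitney identity (probability that a
random case scores above a random control, ties counted half), with the
operating point chosen by Youden's J and a p-value from the normal
approximation to U.  A panel of markers is combined into a single score by
ridge-penalized logistic regression on log2 normalized counts, evaluated
by stratified cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


def _split_labels(labels: np.ndarray | list) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = (y == "case").astype(int)
    else:
        y = y.astype(int)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes (case and control) must be present")
    return y


@dataclass
class RocResult:
    """Per-marker (or panel) ROC summary at the Youden operating point."""

    id: str
    auc: float
    oriented: bool          # True when raw AUC < 0.5 was flipped
    sensitivity: float
    specificity: float
    p_value: float
    n_case: int
    n_control: int


def roc_auc(
    scores: np.ndarray | list[float],
    labels: np.ndarray | list,
    id: str = "",
    orient: bool = True,
) -> RocResult:
    """AUC by the Mann–Whitney identity, operating point by Youden's J.

    With ``orient=True`` (the default) markers that score higher in
    controls are flipped so the reported AUC is ``max(a, 1 − a)``; the
    same marker can be up-regulated in one cancer and down in another, so
    orientation is decided per marker per dataset.
    """
    x = np.asarray(scores, dtype=float)
    y = _split_labels(labels)
    case, ctrl = x[y == 1], x[y == 0]
    n1, n0 = len(case), len(ctrl)
    # Mann-Whitney U via midranks: U = R_case - n1(n1+1)/2; AUC = U/(n1*n0)
    ranks = stats.rankdata(x)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    auc = u / (n1 * n0)
    flipped = orient and auc < 0.5
    if flipped:
        x, auc, u = -x, 1 - auc, n1 * n0 - u
    # normal approximation with tie correction
    _, counts = np.unique(x, return_counts=True)
    n = n1 + n0
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sd = np.sqrt(n1 * n0 / 12 * (n + 1 - tie_term))
    if sd == 0:
        p = 1.0
    else:
        z = (u - n1 * n0 / 2) / sd
        p = float(2 * stats.norm.sf(abs(z)))
    fpr, tpr, _ = roc_curve(y, x)
    j = int(np.argmax(tpr - fpr))
    return RocResult(
        id=id, auc=float(auc), oriented=flipped,
        sensitivity=float(tpr[j]), specificity=float(1 - fpr[j]),
        p_value=p, n_case=n1, n_control=n0,
    )


def bootstrap_auc_ci(
    scores: np.ndarray | list[float],
    labels: np.ndarray | list,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the (oriented) AUC, stratified by class."""
    x = np.asarray(scores, dtype=float)
    y = _split_labels(labels)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    n1, n0 = len(case_idx), len(ctrl_idx)
    bc = x[case_idx[rng.integers(0, n1, (n_boot, n1))]]
    bk = x[ctrl_idx[rng.integers(0, n0, (n_boot, n0))]]
    # vectorized pairwise AUC per bootstrap replicate, ties counted half
    gt = (bc[:, :, None] > bk[:, None, :]).mean(axis=(1, 2))
    eq = (bc[:, :, None] == bk[:, None, :]).mean(axis=(1, 2))
    aucs = gt + 0.5 * eq
    aucs = np.maximum(aucs, 1 - aucs)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def fit_panel_combiner(
    values: pd.DataFrame,
    labels: np.ndarray | list,
    seed: int = 0,
    pseudocount: float = 1.0,
    ridge: float = 1e-3,
    n_folds: int = 5,
) -> dict:
    """Combine panel markers into one diagnostic score.

    Fits a ridge-penalized logistic regression on ``log2(value + pc)`` of
    the panel features (rows of ``values``; columns are samples) and
    evaluates by stratified ``n_folds``-fold cross-validation, averaging
    the fold AUCs.  Features are standardized inside each fit; the ridge
    keeps separable problems finite.

    Returns a dict with ``weights`` (per-feature Series), ``intercept``,
    ``scores`` (in-sample linear predictor per sample) and ``cv_auc``.
    """
    if len(values) < 2:
        raise ValueError("panel combiner needs at least 2 features")
    y = _split_labels(labels)
    x = np.log2(values.to_numpy(dtype=float).T + pseudocount)  # samples × features
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    model = LogisticRegression(C=1.0 / ridge, max_iter=5000)
    model.fit(xs, y)
    scores = xs @ model.coef_[0] + model.intercept_[0]

    n_folds_eff = min(n_folds, int(np.bincount(y).min()))
    if n_folds_eff < 2:
        cv_auc = float("nan")
    else:
        skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
        fold_aucs = []
        for train, test in skf.split(xs, y):
            m = LogisticRegression(C=1.0 / ridge, max_iter=5000)
            m.fit(xs[train], y[train])
            s = xs[test] @ m.coef_[0] + m.intercept_[0]
            fold_aucs.append(roc_auc(s, y[test], orient=False).auc)
        cv_auc = float(np.mean(fold_aucs))
    return {
        "weights": pd.Series(model.coef_[0], index=values.index, name="weight"),
        "intercept": float(model.intercept_[0]),
        "scores": pd.Series(scores, index=values.columns, name="panel_score"),
        "cv_auc": cv_auc,
    }


def pca_variance(values: pd.DataFrame | np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Explained-variance fractions of the column-centered data matrix.

    ``values`` is feature × sample; samples are the observations.  The
    fractions are non-increasing and sum to 1 when all components are
    kept.  A constant matrix yields all-zero fractions.
    """
    arr = np.asarray(values, dtype=float).T  # samples × features
    n, p = arr.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    centered = arr - arr.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    total = (sv**2).sum()
    if total == 0:
        import warnings

        warnings.warn("constant matrix: PCA variance undefined, returning zeros")
        fractions = np.zeros(min(n, p))
    else:
        fractions = sv**2 / total
    k = n_components if n_components is not None else len(fractions)
    return fractions[:k]
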