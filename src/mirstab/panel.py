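"""Outlier-based pan-cancer panel selection.

Step 2 of the procedure: each temporally stable miRNA carries a healthy
reference window ``median ± k·MAD``; in every cancer dataset its
case-vs-control log2 fold change either lies inside the window (normal
behavior) or strictly outside it (an outlier).  Candidates outside their
window — with a significant adjusted p-value where DE results are
available — in strictly more than ``min_outlier_fraction`` of datasets
form the panel, ranked by mean distance from the window borders.

A transcription of the seven-miRNA reference panel (windows plus the
log2FCs observed across eleven cancer datasets) ships with the package as
a worked example; see :func:`load_reference_panel_table`.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger(__name__)


def _check_window(window: tuple[float, float]) -> tuple[float, float]:
    lower, upper = float(window[0]), float(window[1])
    if lower > upper:
        raise ValueError(f"inverted window: lower {lower} > upper {upper}")
    return lower, upper


def is_outlier(fc: float, window: tuple[float, float]) -> bool:
    """True iff ``fc`` lies strictly outside the closed window."""
    lower, upper = _check_window(window)
    return fc < lower or fc > upper


def window_distance(fc: float, window: tuple[float, float]) -> float:
    """Distance from ``fc`` to the window: 0 inside, else gap to the nearer border."""
    lower, upper = _check_window(window)
    if lower <= fc <= upper:
        return 0.0
    return min(abs(fc - lower), abs(fc - upper))


def outlier_fraction(
    fc_by_dataset: pd.Series,
    window: tuple[float, float],
    adj_p_by_dataset: pd.Series | None = None,
    fdr_alpha: float = 0.05,
    all_datasets: list[str] | None = None,
) -> tuple[float, int, int]:
    """Fraction of datasets where a candidate is a significant outlier.

    ``fc_by_dataset`` holds the log2FCs of the datasets where the feature
    is present (passed the expression filter).  When ``adj_p_by_dataset``
    is given, a dataset counts only if ``adj_p < fdr_alpha`` *and* the FC
    is outside the window; otherwise the significance gate is skipped
    (worked-example mode with printed FCs only).  The denominator is the
    number of datasets where the feature is present, or the full
    ``all_datasets`` list when supplied.

    Returns ``(fraction, n_outlier, n_denominator)``.
    """
    fc_by_dataset = fc_by_dataset.dropna()
    if fc_by_dataset.empty:
        raise ValueError("feature absent from every dataset")
    out = fc_by_dataset.apply(lambda fc: is_outlier(fc, window))
    if adj_p_by_dataset is not None:
        sig = adj_p_by_dataset.reindex(fc_by_dataset.index) < fdr_alpha
        out &= sig.fillna(False)
    n_outlier = int(out.sum())
    n_denom = len(all_datasets) if all_datasets is not None else len(fc_by_dataset)
    return n_outlier / n_denom, n_outlier, n_denom


def select_panel(
    stability: pd.DataFrame,
    de_by_dataset: dict[str, pd.DataFrame],
    config: PipelineConfig | None = None,
    denominator: str = "present",
) -> pd.DataFrame:
    """Build the panel report from stability profiles and DE tables.

    Parameters
    ----------
    stability:
        Output of :func:`mirstab.stability.stability_table` (needs columns
        ``lower``, ``upper``, ``mad``, ``stable``).
    de_by_dataset:
        Mapping dataset id → DE table indexed by feature id with columns
        ``log2fc`` and ``adj_p``.
    denominator:
        ``"present"`` divides by the datasets where the candidate passed
        the expression filter; ``"all"`` divides by all datasets.

    Returns
    -------
    DataFrame
        One row per stable candidate, sorted by ``rank_score`` (mean
        window distance) descending: window borders, per-dataset
        ``fc_<dataset>`` and ``out_<dataset>`` columns, outlier counts,
        ``outlier_fraction``, ``rank_score`` and the boolean ``selected``
        call (fraction strictly above ``min_outlier_fraction``).
    """
    cfg = config or PipelineConfig()
    if denominator not in ("present", "all"):
        raise ValueError("denominator must be 'present' or 'all'")
    if not de_by_dataset:
        raise ValueError("no cancer datasets")
    candidates = stability.index[stability["stable"]].tolist()
    datasets = list(de_by_dataset)
    rows = []
    if not candidates:
        logger.warning("select_panel: empty stable set — empty panel report")
    for fid in candidates:
        window = (stability.at[fid, "lower"], stability.at[fid, "upper"])
        fc = pd.Series(
            {ds: de.at[fid, "log2fc"] if fid in de.index else np.nan
             for ds, de in de_by_dataset.items()}
        )
        adj = pd.Series(
            {ds: de.at[fid, "adj_p"] if fid in de.index else np.nan
             for ds, de in de_by_dataset.items()}
        )
        present = fc.dropna().index.tolist()
        if not present:
            logger.warning("select_panel: %s absent from all datasets; skipped", fid)
            continue
        frac, n_out, n_denom = outlier_fraction(
            fc, window, adj, cfg.fdr_alpha,
            all_datasets=datasets if denominator == "all" else None,
        )
        dists = [window_distance(fc[ds], window) for ds in present]
        row = {
            "feature_id": fid,
            "lower": window[0],
            "upper": window[1],
            "mad": stability.at[fid, "mad"],
            "n_datasets_present": len(present),
            "n_outlier": n_out,
            "outlier_fraction": frac,
            "rank_score": float(np.mean(dists)),
            "selected": frac > cfg.min_outlier_fraction,
        }
        for ds in datasets:
            row[f"fc_{ds}"] = fc[ds]
            row[f"out_{ds}"] = (
                bool(is_outlier(fc[ds], window) and adj[ds] < cfg.fdr_alpha)
                if ds in present else False
            )
        rows.append(row)
    cols = ["feature_id", "lower", "upper", "mad", "n_datasets_present",
            "n_outlier", "outlier_fraction", "rank_score", "selected"]
    cols += [f"fc_{ds}" for ds in datasets] + [f"out_{ds}" for ds in datasets]
    report = pd.DataFrame(rows, columns=cols)
    report = report.sort_values(
        ["rank_score", "feature_id"], ascending=[False, True]
    ).set_index("feature_id")
    return report


def select_panel_from_windows(
    windows: pd.DataFrame,
    fc: pd.DataFrame,
    min_outlier_fraction: float = 0.8,
) -> pd.DataFrame:
    """Worked-example selection from printed windows and fold changes.

    ``windows`` has columns ``lower``/``upper``; ``fc`` has one column per
    dataset.  No adjusted p-values are available, so the significance gate
    is skipped and the denominator is the full dataset list.
    """
    rows = []
    for fid in windows.index:
        window = (windows.at[fid, "lower"], windows.at[fid, "upper"])
        frac, n_out, n_denom = outlier_fraction(
            fc.loc[fid], window, all_datasets=list(fc.columns)
        )
        dists = [window_distance(fc.at[fid, ds], window) for ds in fc.columns]
        rows.append({
            "feature_id": fid,
            "lower": window[0],
            "upper": window[1],
            "n_datasets_present": n_denom,
            "n_outlier": n_out,
            "outlier_fraction": frac,
            "rank_score": float(np.mean(dists)),
            "selected": frac > min_outlier_fraction,
        })
    return (
        pd.DataFrame(rows)
        .sort_values(["rank_score", "feature_id"], ascending=[False, True])
        .set_index("feature_id")
    )


def load_reference_panel_table() -> pd.DataFrame:
    """Packaged seven-miRNA reference panel: windows + 11-dataset log2FCs.

    Returns a DataFrame indexed by miRNA with ``lower``/``upper`` window
    borders followed by one log2FC column per cancer dataset.
    """
    with resources.files("mirstab.data").joinpath("table2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)
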