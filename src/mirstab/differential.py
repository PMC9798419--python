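"""Per-dataset case/control differential expression with BH-FDR control.

A deliberately simple DE engine: the effect size is the log2 ratio of
group means of normalized counts, the p-value comes from Welch's
unequal-variance t-test on log2-transformed values, and multiplicity is
handled by the Benjamini–Hochberg step-up adjustment.  Downstream panel
selection consumes only the two quantities this preserves — the log2 fold
change and the adjusted p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleTable
from .normalization import NormalizedMatrix


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, set ``q_(i) = p_(i) * m / i``, enforce monotonicity
    from the largest rank down, cap at 1, and return in the original
    order.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    q = arr[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def de_test(
    nm: NormalizedMatrix,
    st: SampleTable,
    pseudocount: float = 1.0,
    min_group: int = 3,
) -> pd.DataFrame:
    """Case-vs-control DE table for one cancer dataset.

    Per feature: ``log2fc = log2((mean_case + pc) / (mean_control + pc))``
    on normalized counts; ``p_value`` from Welch's t on
    ``log2(value + pc)``; ``adj_p`` by BH over the dataset's features.
    Features where both groups are constant get p = 1 (and log2fc 0 when
    the constants agree).
    """
    dataset = st.frame["dataset_id"].iloc[0]
    case = st.by_condition("case")
    control = st.by_condition("control")
    if len(case) < min_group or len(control) < min_group:
        raise ValueError(
            f"dataset {dataset!r} needs >= {min_group} case and control samples "
            f"(got {len(case)}/{len(control)})"
        )
    vc = nm.values[case].to_numpy()
    vk = nm.values[control].to_numpy()
    log2fc = np.log2((vc.mean(axis=1) + pseudocount) / (vk.mean(axis=1) + pseudocount))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            np.log2(vc + pseudocount), np.log2(vk + pseudocount),
            axis=1, equal_var=False,
        )
        p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: t is 0/0 -> NaN; no evidence either way
    p = np.where(np.isnan(p), 1.0, p)
    base_mean = nm.values[case + control].mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "feature_id": nm.values.index,
            "dataset_id": dataset,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": bh_adjust(p),
        }
    ).set_index("feature_id")
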