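"""End-to-end pipeline: normalization → stability → DE → panel → ROC.

Given a healthy time course and a list of cancer case/control datasets,
each dataset is normalized independently by median-of-ratios; the healthy
cohort is reduced to the features expressed at every time point, scored
for temporal stability, and the stable set is screened across the cancer
datasets for recurrent window outliers.  Selected panel members are
evaluated per dataset by individual ROC/AUC and a cross-validated
ridge-logistic panel score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, evaluation, normalization, panel, stability
from .config import PipelineConfig
from .io import FLOAT_FORMAT, CountMatrix, SampleTable, check_paired

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    stability: pd.DataFrame
    de_by_dataset: dict[str, pd.DataFrame]
    panel: pd.DataFrame
    auc: pd.DataFrame
    stable_ids: set[str]
    selected: set[str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.stability.to_csv(outdir / "stability.tsv", sep="\t", float_format=FLOAT_FORMAT)
        for ds, de in self.de_by_dataset.items():
            de.to_csv(outdir / f"de_{ds}.tsv", sep="\t", float_format=FLOAT_FORMAT)
        self.panel.to_csv(outdir / "panel.tsv", sep="\t", float_format=FLOAT_FORMAT)
        self.auc.to_csv(outdir / "auc.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(
    config: PipelineConfig,
    healthy: tuple[CountMatrix, SampleTable],
    cancer_studies: list[tuple[CountMatrix, SampleTable]],
    outdir: str | Path | None = None,
    evaluate: bool = True,
    n_boot: int = 1000,
) -> PipelineResult:
    """Run all stages in order and optionally write the output tables.

    Deterministic given ``config.rng_seed``: CV folds and bootstrap
    replicates derive their seeds from it, and every other stage is
    deterministic by construction.
    """
    if not cancer_studies:
        raise PipelineError("[input] no cancer datasets")
    h_cm, h_st = healthy
    check_paired(h_cm, h_st)
    for cm, st in cancer_studies:
        check_paired(cm, st)
        for cond in ("case", "control"):
            if not st.by_condition(cond):
                ds = st.frame["dataset_id"].iloc[0]
                raise PipelineError(f"[input] dataset {ds!r} has no {cond} samples")

    with _stage("normalization"):
        h_nm = normalization.normalize(h_cm)
        common = normalization.common_features(h_nm, h_st, config.min_mean_count)
        logger.info("features expressed at all time points: %d/%d",
                    len(common), len(h_nm.feature_ids))
        kept = [f for f in h_nm.feature_ids if f in common]
        h_nm = normalization.NormalizedMatrix(
            h_nm.values.loc[kept], h_nm.size_factors
        )

    with _stage("stability"):
        stab = stability.stability_table(h_nm, h_st, config)
        stable_ids = stability.select_stable(stab["mad"], config.mad_cutoff)
        logger.info("stable miRNAs (MAD < %g): %d", config.mad_cutoff, len(stable_ids))

    de_by_dataset: dict[str, pd.DataFrame] = {}
    norm_by_dataset: dict[str, tuple] = {}
    with _stage("differential"):
        for cm, st in cancer_studies:
            ds = st.frame["dataset_id"].iloc[0]
            nm = normalization.normalize(cm)
            nm = normalization.filter_low_expression(nm, config.min_mean_count)
            de_by_dataset[ds] = differential.de_test(nm, st, config.pseudocount)
            norm_by_dataset[ds] = (nm, st)

    with _stage("panel_selection"):
        report = panel.select_panel(stab, de_by_dataset, config)
        selected = set(report.index[report["selected"]])
        logger.info("panel: %d selected of %d stable candidates",
                    len(selected), len(report))

    auc_rows: list[dict] = []
    if evaluate and selected:
        with _stage("evaluation"):
            seeds = np.random.SeedSequence(config.rng_seed).spawn(len(norm_by_dataset))
            for (ds, (nm, st)), ss in zip(norm_by_dataset.items(), seeds):
                seed = int(ss.generate_state(1)[0] % 2**31)
                labels = np.array([
                    "case" if s in set(st.by_condition("case")) else "control"
                    for s in nm.sample_ids
                ])
                members = [f for f in selected if f in nm.values.index]
                for fid in sorted(members):
                    scores = np.log2(nm.values.loc[fid].to_numpy() + config.pseudocount)
                    r = evaluation.roc_auc(scores, labels, id=fid)
                    lo, hi = evaluation.bootstrap_auc_ci(
                        scores, labels, n_boot=n_boot, seed=seed
                    )
                    auc_rows.append({
                        "dataset_id": ds, "id": fid, "auc": r.auc,
                        "ci_low": lo, "ci_high": hi,
                        "sensitivity": r.sensitivity, "specificity": r.specificity,
                        "p_value": r.p_value,
                    })
                if len(members) >= 2:
                    comb = evaluation.fit_panel_combiner(
                        nm.values.loc[members], labels,
                        seed=seed, pseudocount=config.pseudocount,
                    )
                    r = evaluation.roc_auc(
                        comb["scores"].to_numpy(), labels, id="panel", orient=False
                    )
                    auc_rows.append({
                        "dataset_id": ds, "id": "panel", "auc": comb["cv_auc"],
                        "ci_low": np.nan, "ci_high": np.nan,
                        "sensitivity": r.sensitivity, "specificity": r.specificity,
                        "p_value": r.p_value,
                    })
    auc = pd.DataFrame(
        auc_rows,
        columns=["dataset_id", "id", "auc", "ci_low", "ci_high",
                 "sensitivity", "specificity", "p_value"],
    )

    result = PipelineResult(
        stability=stab, de_by_dataset=de_by_dataset, panel=report,
        auc=auc, stable_ids=stable_ids, selected=selected,
    )
    if outdir is not None:
        result.write(outdir)
    return result
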