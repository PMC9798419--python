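"""Pipeline configuration.

All thresholds of the two-step selection procedure live here: the MAD
consistency constant ``b``, the ``median ± k·MAD`` window multiplier, the
MAD stability cutoff, the low-expression filter, the recurrence fraction
required for panel membership, and the FDR level of the per-dataset
differential-expression gate.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Tunable parameters of the stability/panel-selection pipeline.

    Attributes
    ----------
    pseudocount:
        Added to numerator and denominator means before every log2 ratio.
    min_mean_count:
        Features with mean normalized count below this are discarded
        (applied per time-point group in the healthy cohort, and per
        dataset in the cancer studies).
    mad_b:
        Consistency constant of the MAD; 1.4826 makes the MAD estimate the
        standard deviation under normality.
    window_k:
        Half-width multiplier of the stability window, ``median ± k·MAD``.
    mad_cutoff:
        A miRNA is called temporally stable iff its MAD is strictly below
        this value (log2 units).
    min_outlier_fraction:
        A stable miRNA joins the panel iff it falls outside its window in
        strictly more than this fraction of cancer datasets.
    fdr_alpha:
        BH-adjusted p-value gate for counting a dataset as dysregulated.
    n_clusters:
        Number of temporal-profile clusters.
    cosinor_period_h:
        Period of the cosinor rhythmicity screen, hours.
    cosinor_max_time_h:
        Only time points at or below this feed the cosinor fit; a 24 h
        rhythm is unidentifiable from single samples weeks apart.  Set to
        ``inf`` to fit the full series.
    rng_seed:
        Seed for every stochastic step (simulation, CV folds, bootstrap).
    """

    pseudocount: float = 1.0
    min_mean_count: float = 20.0
    mad_b: float = 1.4826
    window_k: float = 3.0
    mad_cutoff: float = 0.2
    min_outlier_fraction: float = 0.8
    fdr_alpha: float = 0.05
    n_clusters: int = 5
    cosinor_period_h: float = 24.0
    cosinor_max_time_h: float = 72.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "pseudocount", "min_mean_count", "mad_b", "window_k",
            "mad_cutoff", "fdr_alpha", "cosinor_period_h", "cosinor_max_time_h",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("min_outlier_fraction", "fdr_alpha"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
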