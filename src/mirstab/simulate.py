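"""Synthetic healthy time-course and cancer case/control count data.

Emulates the study conditions the pipeline was designed for: whole-blood
small RNA-seq counts from 10 healthy subjects sampled at nine time points
(0, 3, 6, 24, 48, 72 h and days 7/30/60 mapped to 168/720/1440 h), plus
cancer case/control datasets with known per-miRNA log2 effects.  Counts
are negative-binomial with variance ``μ + α·μ²`` (``α`` = dispersion, the
standard RNA-seq overdispersion form), under per-sample library-size
factors ``2^N(0, σ²)``.

Each miRNA follows one of five temporal patterns standing in for the
oscillation classes seen in healthy blood: ``flat`` (stable), ``cosine``
(rhythmic), ``drift`` (slow monotone change), ``spike`` (single-time-point
excursion) and ``noisy`` (flat mean, inflated dispersion).  Ground truth
(pattern assignments and planted cancer effects) is returned alongside
every dataset so recovery can be scored exactly.

A note on rhythm periods: seven of the nine sampling times are congruent
to 0 mod 24 h, so a 24 h cosine is aliased to a near-constant profile on
this grid and is invisible to any dispersion statistic — as are several
other grid-commensurate periods.  Scenario defaults therefore draw cosine
periods uniformly from 90–110 h, a band whose profiles stay visible at
every acrophase; grid-aliased rhythms are exactly what the separate
cosinor screen on the dense 0–72 h points exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import CountMatrix, SampleTable

DEFAULT_TIMEPOINTS_H: tuple[float, ...] = (0, 3, 6, 24, 48, 72, 168, 720, 1440)

PATTERN_KINDS = ("flat", "cosine", "drift", "spike", "noisy")

#: default mix of temporal pattern kinds in a scenario
DEFAULT_PATTERN_MIX: dict[str, float] = {
    "flat": 0.40, "cosine": 0.20, "drift": 0.15, "spike": 0.15, "noisy": 0.10,
}


@dataclass
class PatternSpec:
    """Temporal expression pattern of one miRNA.

    ``baseline_mean`` is the expected normalized count; deviations are in
    log2 units, so the expected count at time ``t`` is
    ``baseline_mean * 2^deviation(t)``.
    """

    kind: str
    baseline_mean: float
    amplitude_log2: float = 0.0
    period_h: float | None = None
    acrophase_h: float | None = None
    spike_timepoint: int | None = None
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.kind == "flat" and self.amplitude_log2 != 0:
            raise ValueError("flat patterns must have amplitude_log2 = 0")
        if self.amplitude_log2 < 0:
            raise ValueError("amplitude_log2 must be >= 0")
        if self.kind == "cosine" and (self.period_h is None or self.period_h <= 0):
            raise ValueError("cosine patterns need a positive period_h")
        if self.kind == "spike" and self.spike_timepoint is None:
            raise ValueError("spike patterns need spike_timepoint")


@dataclass
class ScenarioTruth:
    """Ground-truth ledger for recovery tests."""

    stable_ids: set[str]
    pattern_of: dict[str, PatternSpec]
    planted_panel: set[str] = field(default_factory=set)
    effect_log2: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.planted_panel <= self.stable_ids:
            raise ValueError("planted_panel must be a subset of the stable (flat) set")

    def kinds(self) -> pd.Series:
        return pd.Series({m: s.kind for m, s in self.pattern_of.items()})


def pattern_mean(
    spec: PatternSpec,
    t: float,
    timepoints_h: tuple[float, ...] | list[float] = DEFAULT_TIMEPOINTS_H,
) -> float:
    """Expected normalized count of a pattern at time ``t`` (hours).

    Deviations: 0 (flat, noisy);
    ``A·cos(2π(t − acrophase)/period)`` (cosine);
    ``A·t/t_max`` (drift);
    ``A`` at the spike time point, else 0 (spike).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    a = spec.amplitude_log2
    if spec.kind in ("flat", "noisy"):
        dev = 0.0
    elif spec.kind == "cosine":
        phase = spec.acrophase_h or 0.0
        dev = a * np.cos(2 * np.pi * (t - phase) / spec.period_h)
    elif spec.kind == "drift":
        t_max = max(timepoints_h)
        dev = a * t / t_max
    else:  # spike
        dev = a if t == timepoints_h[spec.spike_timepoint] else 0.0
    return float(spec.baseline_mean * 2.0**dev)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB counts with variance μ + α·μ² via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(dispersion, dtype=float)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(np.broadcast_to(n, mean.shape), p)


def generate_healthy_timecourse(
    specs: dict[str, PatternSpec],
    n_subjects: int = 10,
    timepoints_h: tuple[float, ...] | list[float] = DEFAULT_TIMEPOINTS_H,
    library_size_log2_sd: float = 0.25,
    seed: int = 0,
    dataset_id: str = "healthy",
) -> tuple[CountMatrix, SampleTable, ScenarioTruth]:
    """Simulate the healthy cohort: ``n_subjects`` sampled at each time point.

    Every sample draws a library-size factor ``2^N(0, σ²)``; each miRNA's
    count is NB with mean ``factor · pattern_mean(spec, t)``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    timepoints_h = tuple(float(t) for t in timepoints_h)
    if len(timepoints_h) < 3:
        raise ValueError("need at least 3 time points")
    rng = np.random.default_rng(seed)
    mirnas = list(specs)
    sample_ids, rows = [], []
    for t in timepoints_h:
        for subj in range(1, n_subjects + 1):
            sid = f"S{subj:02d}_t{t:g}h"
            sample_ids.append(sid)
            rows.append((sid, f"S{subj:02d}", t, "healthy", dataset_id))
    lib = 2.0 ** rng.normal(0.0, library_size_log2_sd, len(sample_ids))
    mu = np.empty((len(mirnas), len(sample_ids)))
    disp = np.empty_like(mu)
    for i, m in enumerate(mirnas):
        spec = specs[m]
        per_t = {t: pattern_mean(spec, t, timepoints_h) for t in timepoints_h}
        for j, (_, _, t, _, _) in enumerate(rows):
            mu[i, j] = per_t[t] * lib[j]
        disp[i, :] = spec.dispersion
    counts = _nb_draw(rng, mu, disp)
    cm = CountMatrix(pd.DataFrame(counts, index=mirnas, columns=sample_ids))
    st = SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "timepoint_h", "condition", "dataset_id"]
    ))
    truth = ScenarioTruth(
        stable_ids={m for m, s in specs.items() if s.kind == "flat"},
        pattern_of=dict(specs),
    )
    return cm, st, truth


def generate_cancer_study(
    specs: dict[str, PatternSpec],
    planted_effects: dict[str, float],
    n_case: int = 20,
    n_control: int = 20,
    library_size_log2_sd: float = 0.25,
    seed: int = 0,
    dataset_id: str = "cancer",
) -> tuple[CountMatrix, SampleTable]:
    """Simulate one case/control dataset.

    Controls draw at each miRNA's ``baseline_mean``; cases at
    ``baseline_mean · 2^effect`` (effect 0 when unplanted).
    """
    if n_case < 3 or n_control < 3:
        raise ValueError("need at least 3 case and 3 control samples")
    unknown = set(planted_effects) - set(specs)
    if unknown:
        raise ValueError(f"effects planted for unknown miRNAs: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    mirnas = list(specs)
    sample_ids, rows = [], []
    for i in range(1, n_case + 1):
        sid = f"{dataset_id}_case{i:02d}"
        sample_ids.append(sid)
        rows.append((sid, sid, np.nan, "case", dataset_id))
    for i in range(1, n_control + 1):
        sid = f"{dataset_id}_ctrl{i:02d}"
        sample_ids.append(sid)
        rows.append((sid, sid, np.nan, "control", dataset_id))
    lib = 2.0 ** rng.normal(0.0, library_size_log2_sd, len(sample_ids))
    is_case = np.array([r[3] == "case" for r in rows])
    mu = np.empty((len(mirnas), len(sample_ids)))
    disp = np.empty_like(mu)
    for i, m in enumerate(mirnas):
        spec = specs[m]
        eff = planted_effects.get(m, 0.0)
        base = spec.baseline_mean
        mu[i, :] = np.where(is_case, base * 2.0**eff, base) * lib
        disp[i, :] = spec.dispersion
    counts = _nb_draw(rng, mu, disp)
    cm = CountMatrix(pd.DataFrame(counts, index=mirnas, columns=sample_ids))
    st = SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "timepoint_h", "condition", "dataset_id"]
    ))
    return cm, st


@dataclass
class Scenario:
    """One full synthetic study: healthy cohort + cancer datasets + truth."""

    healthy: tuple[CountMatrix, SampleTable]
    cancer_studies: list[tuple[CountMatrix, SampleTable]]
    truth: ScenarioTruth


def default_pattern_specs(
    n_mirnas: int,
    rng: np.random.Generator,
    pattern_mix: dict[str, float] | None = None,
    baseline_range: tuple[float, float] = (100.0, 1000.0),
    dispersion: float = 0.05,
    noisy_dispersion: float = 0.5,
    cosine_period_range_h: tuple[float, float] = (90.0, 110.0),
    cosine_amplitude_range_log2: tuple[float, float] = (0.5, 1.5),
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H,
) -> dict[str, PatternSpec]:
    """Assign pattern kinds in the default proportions with random shapes."""
    mix = pattern_mix or DEFAULT_PATTERN_MIX
    if abs(sum(mix.values()) - 1) > 1e-9:
        raise ValueError("pattern mix must sum to 1")
    counts = {k: int(round(frac * n_mirnas)) for k, frac in mix.items()}
    counts["flat"] += n_mirnas - sum(counts.values())  # remainder to flat
    kinds = [k for k, c in counts.items() for _ in range(c)]
    rng.shuffle(kinds)
    lo, hi = np.log(baseline_range[0]), np.log(baseline_range[1])
    specs: dict[str, PatternSpec] = {}
    for i, kind in enumerate(kinds):
        name = f"syn-miR-{i + 1:03d}"
        base = float(np.exp(rng.uniform(lo, hi)))
        if kind == "flat":
            specs[name] = PatternSpec("flat", base, dispersion=dispersion)
        elif kind == "cosine":
            period = float(rng.uniform(*cosine_period_range_h))
            specs[name] = PatternSpec(
                "cosine", base,
                amplitude_log2=float(rng.uniform(*cosine_amplitude_range_log2)),
                period_h=period, acrophase_h=float(rng.uniform(0, period)),
                dispersion=dispersion,
            )
        elif kind == "drift":
            specs[name] = PatternSpec(
                "drift", base, amplitude_log2=float(rng.uniform(0.5, 2.0)),
                dispersion=dispersion,
            )
        elif kind == "spike":
            specs[name] = PatternSpec(
                "spike", base, amplitude_log2=float(rng.uniform(1.0, 2.0)),
                spike_timepoint=int(rng.integers(0, len(timepoints_h))),
                dispersion=dispersion,
            )
        else:
            specs[name] = PatternSpec("noisy", base, dispersion=noisy_dispersion)
    return specs


def generate_scenario(
    config: PipelineConfig | None = None,
    n_mirnas: int = 200,
    n_datasets: int = 11,
    panel_size: int = 7,
    effect_range_log2: tuple[float, float] = (1.5, 2.5),
    n_case: int = 20,
    n_control: int = 20,
    n_subjects: int = 10,
    seed: int | None = None,
) -> Scenario:
    """One-call bundle: healthy time course, cancer studies and ground truth.

    Panel members are drawn from the flat miRNAs and given an effect in
    every cancer dataset with magnitude uniform in ``effect_range_log2``
    and independent random sign (the same marker may go up in one cancer
    and down in another).  The minimum effect magnitude must clear the
    identifiability bound ``window_k · mad_cutoff + 0.3`` — the widest
    window a stable miRNA can carry, plus margin — so recovery has a
    definite answer.
    """
    cfg = config or PipelineConfig()
    seed = cfg.rng_seed if seed is None else seed
    if effect_range_log2[0] > effect_range_log2[1] or effect_range_log2[0] < 0:
        raise ValueError("effect_range_log2 must be 0 <= lo <= hi")
    bound = cfg.window_k * cfg.mad_cutoff + 0.3
    if panel_size > 0 and effect_range_log2[0] < bound:
        raise ValueError(
            f"minimum |effect| {effect_range_log2[0]} is below the "
            f"identifiability bound {bound:.2f} (window_k*mad_cutoff + 0.3)"
        )
    rng = np.random.default_rng(seed)
    specs = default_pattern_specs(n_mirnas, rng)
    flats = sorted(m for m, s in specs.items() if s.kind == "flat")
    if panel_size > len(flats):
        raise ValueError(f"panel_size {panel_size} exceeds {len(flats)} flat miRNAs")
    panel = (
        {str(m) for m in rng.choice(flats, size=panel_size, replace=False)}
        if panel_size else set()
    )

    healthy_cm, healthy_st, truth = generate_healthy_timecourse(
        specs, n_subjects=n_subjects, seed=int(rng.integers(2**31)),
    )
    dataset_ids = [f"cancer{d + 1:02d}" for d in range(n_datasets)]
    effect_log2: dict[tuple[str, str], float] = {}
    studies = []
    for ds in dataset_ids:
        effects = {}
        for m in sorted(panel):
            mag = float(rng.uniform(*effect_range_log2))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[m] = sign * mag
            effect_log2[(m, ds)] = effects[m]
        cm, st = generate_cancer_study(
            specs, effects, n_case=n_case, n_control=n_control,
            seed=int(rng.integers(2**31)), dataset_id=ds,
        )
        studies.append((cm, st))
    truth.planted_panel = panel
    truth.effect_log2 = effect_log2
    return Scenario(
        healthy=(healthy_cm, healthy_st), cancer_studies=studies, truth=truth,
    )
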