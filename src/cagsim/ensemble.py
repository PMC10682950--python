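"""Ensembles of lineages: fate aggregation, comparison, sensitivity sweeps.

The study design is an ensemble of independent lineages (default 1,000) per
ancestral expansion, each run to elimination, fixation or the generation
horizon. This module derives independent per-lineage random streams from a
single master seed, aggregates fates and event statistics, compares two
diseases with a two-proportion test, and sweeps the imputed fitness SD for
sensitivity analysis.

Seed derivation: ``numpy.random.SeedSequence(master_seed).spawn(n)`` gives
lineage *i* the *i*-th child sequence, so results are independent of
execution order and reproducible to the bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fertility import FertilitySchedule
from .lineage import (
    ELIMINATED,
    FIXED_HELD,
    FIXED_THEN_EXTINCT,
    PERSISTING,
    LineageOutcome,
    simulate_lineage,
)
from .params import DiseaseConfig, validate_config

__all__ = [
    "EnsembleSummary",
    "run_ensemble",
    "summarize",
    "sensitivity_sweep",
    "compare_diseases",
]


@dataclass(frozen=True)
class EnsembleSummary:
    """Fate counts and event statistics for one ensemble.

    Statistics of empty strata (e.g. fixation statistics when no lineage
    fixed) are ``None``, never zero. Ranges are (min, max); medians use the
    standard mid-point convention for even counts.
    """

    n_lineages: int
    n_eliminated: int
    n_fixed_then_extinct: int
    n_fixed_held: int
    n_persisting: int
    n_fixed: int  # n_fixed_then_extinct + n_fixed_held
    n_expanded_at_horizon: Optional[int]
    elimination_generation_median: Optional[float] = None
    elimination_generation_range: Optional[tuple[float, float]] = None
    fixation_generation_median: Optional[float] = None
    fixation_generation_range: Optional[tuple[float, float]] = None
    repeat_at_elimination_median: Optional[float] = None
    repeat_at_elimination_range: Optional[tuple[float, float]] = None
    repeat_at_fixation_median: Optional[float] = None
    repeat_at_fixation_mean: Optional[float] = None
    repeat_at_fixation_range: Optional[tuple[float, float]] = None
    ao_at_fixation_mean: Optional[float] = None
    ao_at_fixation_range: Optional[tuple[float, float]] = None
    frequency_at_horizon_median: Optional[float] = None
    frequency_at_horizon_iqr: Optional[tuple[float, float]] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleSummary":
        d = dict(d)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @property
    def status_counts(self) -> dict[str, int]:
        return {
            ELIMINATED: self.n_eliminated,
            FIXED_THEN_EXTINCT: self.n_fixed_then_extinct,
            FIXED_HELD: self.n_fixed_held,
            PERSISTING: self.n_persisting,
        }


def _median_range(values: Sequence[float]):
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr)), (float(arr.min()), float(arr.max()))


def summarize(outcomes: Sequence[LineageOutcome]) -> EnsembleSummary:
    """Aggregate lineage fates into the study's summary statistics."""
    if len(outcomes) == 0:
        raise ValueError("cannot summarize an empty list of outcomes")
    by_status = {s: [o for o in outcomes if o.status == s] for s in
                 (ELIMINATED, FIXED_THEN_EXTINCT, FIXED_HELD, PERSISTING)}
    eliminated = by_status[ELIMINATED]
    fixed = by_status[FIXED_THEN_EXTINCT] + by_status[FIXED_HELD]
    persisting = by_status[PERSISTING]

    kw: dict = {}
    if eliminated:
        kw["elimination_generation_median"], kw["elimination_generation_range"] = (
            _median_range([o.terminal_generation for o in eliminated])
        )
        kw["repeat_at_elimination_median"], kw["repeat_at_elimination_range"] = (
            _median_range([o.repeat_at_event for o in eliminated])
        )
    if fixed:
        kw["fixation_generation_median"], kw["fixation_generation_range"] = (
            _median_range([o.fixation_generation for o in fixed])
        )
        reps = [o.repeat_at_event for o in fixed]
        kw["repeat_at_fixation_median"], kw["repeat_at_fixation_range"] = _median_range(reps)
        kw["repeat_at_fixation_mean"] = float(np.mean(reps))
        aos = [o.ao_at_event for o in fixed]
        kw["ao_at_fixation_mean"] = float(np.mean(aos))
        kw["ao_at_fixation_range"] = (float(np.min(aos)), float(np.max(aos)))
    n_expanded = None
    if persisting:
        freqs = np.asarray([o.frequency_at_horizon for o in persisting], dtype=float)
        kw["frequency_at_horizon_median"] = float(np.median(freqs))
        q1, q3 = np.percentile(freqs, [25, 75])
        kw["frequency_at_horizon_iqr"] = (float(q1), float(q3))
        n_expanded = sum(bool(o.expanded_at_horizon) for o in persisting)

    return EnsembleSummary(
        n_lineages=len(outcomes),
        n_eliminated=len(eliminated),
        n_fixed_then_extinct=len(by_status[FIXED_THEN_EXTINCT]),
        n_fixed_held=len(by_status[FIXED_HELD]),
        n_persisting=len(persisting),
        n_fixed=len(fixed),
        n_expanded_at_horizon=n_expanded,
        **kw,
    )


def run_ensemble(
    cfg: DiseaseConfig,
    s: FertilitySchedule,
    n: int,
    master_seed: int,
) -> tuple[list[LineageOutcome], EnsembleSummary]:
    """Run ``n`` independent lineages and summarize their fates.

    Lineage streams are spawned from ``SeedSequence(master_seed)``, so the
    run is embarrassingly parallel in principle and bit-reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    validate_config(cfg)
    children = np.random.SeedSequence(master_seed).spawn(n)
    outcomes = [simulate_lineage(cfg, s, child) for child in children]
    return outcomes, summarize(outcomes)


def sensitivity_sweep(
    cfg: DiseaseConfig,
    s: FertilitySchedule,
    fitness_sd_values: Sequence[float],
    n: int,
    master_seed: int,
    per_regime: Optional[str] = None,
) -> list[tuple[float, EnsembleSummary]]:
    """Re-run the ensemble under alternative imputed fitness SDs.

    By default each SD value replaces the fitness SD of both the expanded and
    the normal regime (the imputation applies to all allele categories);
    ``per_regime`` = ``"expanded"`` or ``"normal"`` restricts the sweep to
    one regime. The same master seed is reused for every value, so rows
    differ only through the SD.
    """
    results = []
    for sd in fitness_sd_values:
        if sd < 0:
            raise ValueError(f"fitness SD must be >= 0, got {sd}")
        if per_regime is None:
            swept = cfg.with_fitness_sd(sd)
        elif per_regime == "expanded":
            swept = replace(cfg, expanded=replace(cfg.expanded, fitness_sd=sd))
        elif per_regime == "normal":
            swept = replace(cfg, normal=replace(cfg.normal, fitness_sd=sd))
        else:
            raise ValueError(f"per_regime must be None, 'expanded' or 'normal', got {per_regime!r}")
        _, summary = run_ensemble(swept, s, n, master_seed)
        results.append((float(sd), summary))
    return results


def _two_proportion_test(x1: int, x2: int, n: int) -> float:
    """Two-proportion chi-square with continuity correction; p-value."""
    table = np.array([[x1, n - x1], [x2, n - x2]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0  # identical degenerate margins: no evidence of difference
    res = stats.chi2_contingency(table, correction=True)
    return float(res.pvalue)


def compare_diseases(
    summary_a: EnsembleSummary, summary_b: EnsembleSummary,
    label_a: str = "a", label_b: str = "b",
) -> pd.DataFrame:
    """Side-by-side fate counts with two-proportion tests.

    Returns a table with one row per fate class (plus the combined fixation
    count), the two ensembles' counts, and the chi-square p-value for the
    eliminated and persisting fractions.
    """
    if summary_a.n_lineages != summary_b.n_lineages:
        raise ValueError(
            "ensembles must have equal n to compare: "
            f"{summary_a.n_lineages} != {summary_b.n_lineages}"
        )
    n = summary_a.n_lineages
    rows = []
    for status in (ELIMINATED, FIXED_THEN_EXTINCT, FIXED_HELD, PERSISTING):
        ca = summary_a.status_counts[status]
        cb = summary_b.status_counts[status]
        p = (
            _two_proportion_test(ca, cb, n)
            if status in (ELIMINATED, PERSISTING)
            else np.nan
        )
        rows.append({"fate": status, label_a: ca, label_b: cb, "p_value": p})
    rows.append(
        {
            "fate": "fixed_total",
            label_a: summary_a.n_fixed,
            label_b: summary_b.n_fixed,
            "p_value": _two_proportion_test(summary_a.n_fixed, summary_b.n_fixed, n),
        }
    )
    return pd.DataFrame(rows)
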