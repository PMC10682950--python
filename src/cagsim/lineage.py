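"""Single-lineage engine: the adapted allele-frequency recursion.

One lineage descends from a single de novo expansion carrier. Each
generation, four transmission variables are drawn from the Gaussian regime
of the allele class (expanded or normal), the repeat length and implied age
at onset (AO) are updated, and the allele frequency advances through the
adapted selection recursion

    p' = p * w * antcoeff * 2k

where *w* is relative fitness, *k* the segregation coefficient and
*antcoeff* the anticipation coefficient (1 while the allele is in the normal
range). The recursion drops the homozygote and wild-type terms of the
classical diploid selection equation: expanded alleles are vanishingly rare
(p^2 ~ 0) and fully dominant, so selection acts through heterozygous
carriers only.

A lineage terminates when its frequency reaches exactly 0 (eliminated) or,
after fixation (frequency 1), when continuing repeat expansion pushes the
implied AO below the start of the reproductive window (extinct after
fixation). Fixation pins the frequency at 1 but repeat/AO dynamics continue
to the generation horizon. Lineages reaching the horizon with 0 < p < 1
persist; no floor is placed on small frequencies, which can legitimately
reach ~1e-100 in double precision.

Modelling choices worth noting (details in docs/methods.md):

* Repeat lengths are continuous reals, not integers — the per-transmission
  instability is a Gaussian mean effect, not a discrete mutation count.
* Gaussian draws are untruncated; a rare non-positive sampled w or k drives
  p to 0 and counts as elimination.
* The transmission draw comes from the regime the allele is in when
  transmitted (the parent's class, i.e. the regime entering the step);
  the anticipation penalty applies to the class of the transmitted allele
  (after the instability step). ``DiseaseConfig.draw_regime`` can switch the
  draw to the post-step class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .fertility import FertilitySchedule, anticipation_coefficient
from .params import AlleleRegimeParams, DiseaseConfig, GenerationDraw

__all__ = [
    "LineageState",
    "LineageOutcome",
    "TrajectoryRecord",
    "frequency_update",
    "draw_generation_params",
    "step_lineage",
    "simulate_lineage",
    "classify",
    "ELIMINATED",
    "FIXED_THEN_EXTINCT",
    "FIXED_HELD",
    "PERSISTING",
    "STATUSES",
]

ELIMINATED = "eliminated"
FIXED_THEN_EXTINCT = "fixed_then_extinct"
FIXED_HELD = "fixed_held"
PERSISTING = "persisting"
STATUSES = (ELIMINATED, FIXED_THEN_EXTINCT, FIXED_HELD, PERSISTING)

EXPANDED = "expanded"
NORMAL = "normal"


@dataclass(frozen=True)
class LineageState:
    """Per-generation state of one lineage (generation 0 is the ancestor)."""

    generation: int
    frequency: float
    repeat_length: float
    ao: float
    regime: str  # "expanded" | "normal"
    fixed: bool = False
    fixation_generation: Optional[int] = None


@dataclass(frozen=True)
class TrajectoryRecord:
    generation: int
    frequency: float
    repeat_length: float
    ao: float
    regime: str
    fixed: bool


@dataclass(frozen=True)
class LineageOutcome:
    """Fate of one simulated lineage.

    ``repeat_at_event``/``ao_at_event`` refer to the terminal event: the
    generation of elimination for eliminated lineages, the generation of
    fixation for fixed ones. ``expanded_at_horizon`` and
    ``frequency_at_horizon`` are populated for persisting lineages.
    """

    status: str
    terminal_generation: int
    fixation_generation: Optional[int]
    repeat_at_event: Optional[float]
    ao_at_event: Optional[float]
    expanded_at_horizon: Optional[bool]
    frequency_at_horizon: Optional[float]
    repeat_at_horizon: Optional[float]
    trajectory: tuple[TrajectoryRecord, ...] = field(repr=False)

    @property
    def reached_fixation(self) -> bool:
        return self.fixation_generation is not None


def frequency_update(p: float, w: float, antcoeff: float, k: float) -> float:
    """One application of the adapted recursion p' = p*w*antcoeff*2k.

    The result is clamped to [0, 1]; non-positive products collapse to
    exactly 0 (elimination) and products >= 1 to exactly 1 (fixation).
    """
    v = p * w * antcoeff * (2.0 * k)
    if v <= 0.0:
        return 0.0
    if v >= 1.0:
        return 1.0
    return v


def draw_generation_params(
    rng: np.random.Generator, regime_params: AlleleRegimeParams
) -> GenerationDraw:
    """Four independent, untruncated Gaussian draws for one transmission."""
    rp = regime_params
    return GenerationDraw(
        w=rng.normal(rp.fitness_mean, rp.fitness_sd),
        k=rng.normal(rp.segregation_mean, rp.segregation_sd),
        delta_repeats=rng.normal(rp.instability_mean, rp.instability_sd),
        ao_slope=rng.normal(rp.ao_slope_mean, rp.ao_slope_sd),
    )


def _regime_of(repeat_length: float, cfg: DiseaseConfig) -> str:
    # inclusive threshold: repeat >= threshold is pathogenic
    return EXPANDED if repeat_length >= cfg.pathogenic_threshold else NORMAL


def step_lineage(
    state: LineageState,
    draw: GenerationDraw,
    cfg: DiseaseConfig,
    s: FertilitySchedule,
) -> LineageState:
    """Advance one generation.

    Repeat length moves by the sampled instability; the implied AO moves by
    minus instability times the sampled AO slope (so contractions raise the
    AO). The anticipation coefficient uses the post-step allele class: it is
    exactly 1 while the transmitted allele is in the normal range. If the
    lineage is already fixed, the frequency stays pinned at 1 and only the
    repeat/AO dynamics advance.
    """
    repeat = state.repeat_length + draw.delta_repeats
    ao = state.ao - draw.delta_repeats * draw.ao_slope
    regime = _regime_of(repeat, cfg)
    if state.fixed:
        freq = 1.0
    else:
        if regime == EXPANDED:
            antcoeff = anticipation_coefficient(s, ao, cfg.post_onset_birth_fraction)
        else:
            antcoeff = 1.0
        freq = frequency_update(state.frequency, draw.w, antcoeff, draw.k)
    fixed = state.fixed or freq >= 1.0
    fix_gen = state.fixation_generation
    if fixed and fix_gen is None:
        fix_gen = state.generation + 1
    return LineageState(
        generation=state.generation + 1,
        frequency=1.0 if fixed else freq,
        repeat_length=repeat,
        ao=ao,
        regime=regime,
        fixed=fixed,
        fixation_generation=fix_gen,
    )


def classify(
    *,
    frequency: float,
    fixed: bool,
    extinct_after_fixation: bool,
    at_horizon: bool,
) -> str:
    """Map terminal facts to exactly one of the four fate statuses."""
    if fixed:
        return FIXED_THEN_EXTINCT if extinct_after_fixation else FIXED_HELD
    if frequency <= 0.0:
        return ELIMINATED
    if at_horizon:
        return PERSISTING
    raise ValueError("lineage is not terminal: frequency in (0,1), not fixed, not at horizon")


def simulate_lineage(
    cfg: DiseaseConfig,
    s: FertilitySchedule,
    seed: Union[int, np.random.SeedSequence, np.random.Generator],
) -> LineageOutcome:
    """Simulate one lineage from the ancestral carrier to its fate.

    The ancestor (generation 0) carries the configured ancestral repeat and
    AO at the configured initial frequency. Iteration stops at elimination
    (frequency exactly 0), at post-fixation extinction (AO at or below the
    window start while expanded), or at the generation horizon.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    window_min = cfg.reproductive_window[0]

    state = LineageState(
        generation=0,
        frequency=cfg.initial_frequency,
        repeat_length=cfg.ancestral_repeat,
        ao=cfg.ancestral_ao,
        regime=_regime_of(cfg.ancestral_repeat, cfg),
    )
    traj = [
        TrajectoryRecord(
            state.generation, state.frequency, state.repeat_length, state.ao,
            state.regime, state.fixed,
        )
    ]
    repeat_at_event: Optional[float] = None
    ao_at_event: Optional[float] = None

    for _ in range(cfg.max_generations):
        if cfg.draw_regime == "parental":
            rp = cfg.expanded if state.regime == EXPANDED else cfg.normal
            draw = draw_generation_params(rng, rp)
        else:  # offspring: regime after the instability step supplies the draw
            rp = cfg.expanded if state.regime == EXPANDED else cfg.normal
            draw = draw_generation_params(rng, rp)
            post_regime = _regime_of(state.repeat_length + draw.delta_repeats, cfg)
            if (post_regime == EXPANDED) != (state.regime == EXPANDED):
                rp2 = cfg.expanded if post_regime == EXPANDED else cfg.normal
                draw = replace(
                    draw,
                    w=rng.normal(rp2.fitness_mean, rp2.fitness_sd),
                    k=rng.normal(rp2.segregation_mean, rp2.segregation_sd),
                )
        newly_fixed_before = state.fixed
        state = step_lineage(state, draw, cfg, s)
        traj.append(
            TrajectoryRecord(
                state.generation, state.frequency, state.repeat_length, state.ao,
                state.regime, state.fixed,
            )
        )
        if not state.fixed and state.frequency <= 0.0:
            repeat_at_event = state.repeat_length
            ao_at_event = state.ao
            return LineageOutcome(
                status=ELIMINATED,
                terminal_generation=state.generation,
                fixation_generation=None,
                repeat_at_event=repeat_at_event,
                ao_at_event=ao_at_event,
                expanded_at_horizon=None,
                frequency_at_horizon=None,
                repeat_at_horizon=None,
                trajectory=tuple(traj),
            )
        if state.fixed and not newly_fixed_before:
            repeat_at_event = state.repeat_length
            ao_at_event = state.ao
        if state.fixed and state.regime == EXPANDED and state.ao <= window_min:
            return LineageOutcome(
                status=FIXED_THEN_EXTINCT,
                terminal_generation=state.generation,
                fixation_generation=state.fixation_generation,
                repeat_at_event=repeat_at_event,
                ao_at_event=ao_at_event,
                expanded_at_horizon=None,
                frequency_at_horizon=None,
                repeat_at_horizon=None,
                trajectory=tuple(traj),
            )

    # horizon reached
    if state.fixed:
        return LineageOutcome(
            status=FIXED_HELD,
            terminal_generation=state.generation,
            fixation_generation=state.fixation_generation,
            repeat_at_event=repeat_at_event,
            ao_at_event=ao_at_event,
            expanded_at_horizon=None,
            frequency_at_horizon=None,
            repeat_at_horizon=state.repeat_length,
            trajectory=tuple(traj),
        )
    return LineageOutcome(
        status=PERSISTING,
        terminal_generation=state.generation,
        fixation_generation=None,
        repeat_at_event=None,
        ao_at_event=None,
        expanded_at_horizon=state.regime == EXPANDED,
        frequency_at_horizon=state.frequency,
        repeat_at_horizon=state.repeat_length,
        trajectory=tuple(traj),
    )
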