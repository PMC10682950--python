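"""Domain types and packaged disease presets.

The simulator tracks one lineage of a dominant expanded CAG-repeat allele.
Each allele regime (expanded above the pathogenic threshold, normal below it)
is summarised by four Gaussian-distributed transmission variables: relative
fitness *w* of carriers, segregation coefficient *k* (probability that the
tracked allele is transmitted in a meiosis; 0.5 is Mendelian), meiotic
instability (mean change in repeat number per transmission), and the
age-at-onset reduction per added repeat (years/repeat, from locus-specific
regressions of onset age on expanded repeat length).

Two curated presets ship: ``sca2`` (*ATXN2*) and ``sca3`` (*ATXN3*/MJD).
Values are literature meta-analysis means and SDs; a few SDs are imputed
(fitness SDs of 0.25 for all regimes, the SCA2 segregation SD, and the
normal-*ATXN3* instability SD of 0.468 borrowed from *ATXN2*) — see
docs/methods.md for provenance notes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Union

__all__ = [
    "AlleleRegimeParams",
    "DiseaseConfig",
    "GenerationDraw",
    "ConfigError",
    "preset",
    "available_presets",
    "validate_config",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
]


class ConfigError(ValueError):
    """Raised when a configuration violates a type invariant."""


@dataclass(frozen=True)
class AlleleRegimeParams:
    """Gaussian mean/SD bundle for one allele regime.

    ``ao_slope_*`` is the onset-age reduction per added repeat. It is
    estimated on expanded alleles; the presets copy the disease's expanded
    slope into the normal regime so that the implied onset age keeps tracking
    repeat length through contractions below the pathogenic threshold.
    """

    fitness_mean: float
    fitness_sd: float
    segregation_mean: float
    segregation_sd: float
    instability_mean: float
    instability_sd: float
    ao_slope_mean: float = 0.0
    ao_slope_sd: float = 0.0

    def validation_errors(self, prefix: str = "") -> list[str]:
        errs = []
        for name in ("fitness_sd", "segregation_sd", "instability_sd", "ao_slope_sd"):
            v = getattr(self, name)
            if v < 0:
                errs.append(f"{prefix}{name} must be >= 0, got {v}")
        if not (0.0 < self.segregation_mean < 1.0):
            errs.append(
                f"{prefix}segregation_mean must be in (0,1), got {self.segregation_mean}"
            )
        if not self.fitness_mean > 0:
            errs.append(f"{prefix}fitness_mean must be > 0, got {self.fitness_mean}")
        return errs


@dataclass(frozen=True)
class GenerationDraw:
    """One generation's sampled transmission variables (untruncated)."""

    w: float
    k: float
    delta_repeats: float
    ao_slope: float


@dataclass(frozen=True)
class DiseaseConfig:
    """Full preset for one locus plus run controls.

    Repeat lengths are carried as continuous reals; ``pathogenic_threshold``
    is the inclusive lower bound of the pathogenic range (repeat >= threshold
    means expanded). ``post_onset_birth_fraction`` is the fraction of births
    that occur after parental symptom onset and is added to the anticipation
    coefficient. ``draw_regime`` selects which allele class supplies the
    transmission draw: ``"parental"`` (the regime entering the step, default)
    or ``"offspring"`` (the regime after the instability step).
    """

    name: str
    pathogenic_threshold: float
    ancestral_repeat: float
    ancestral_ao: float
    post_onset_birth_fraction: float
    expanded: AlleleRegimeParams
    normal: AlleleRegimeParams
    initial_frequency: float = 1e-6
    max_generations: int = 650
    reproductive_window: tuple[float, float] = (12.0, 50.0)
    draw_regime: str = "parental"

    def with_fitness_sd(self, sd: float) -> "DiseaseConfig":
        """Copy of this config with both regimes' fitness SD replaced."""
        return replace(
            self,
            expanded=replace(self.expanded, fitness_sd=sd),
            normal=replace(self.normal, fitness_sd=sd),
        )

    def with_zero_sds(self) -> "DiseaseConfig":
        """Copy with every SD set to zero (deterministic mean dynamics)."""

        def degenerate(rp: AlleleRegimeParams) -> AlleleRegimeParams:
            return replace(
                rp, fitness_sd=0.0, segregation_sd=0.0, instability_sd=0.0, ao_slope_sd=0.0
            )

        return replace(
            self, expanded=degenerate(self.expanded), normal=degenerate(self.normal)
        )


_PRESETS: dict[str, DiseaseConfig] = {
    "sca2": DiseaseConfig(
        name="sca2",
        pathogenic_threshold=34.0,
        ancestral_repeat=34.0,
        ancestral_ao=55.0,
        post_onset_birth_fraction=0.08,
        expanded=AlleleRegimeParams(
            fitness_mean=1.50,
            fitness_sd=0.25,
            segregation_mean=0.404,
            segregation_sd=0.085,
            instability_mean=2.42,
            instability_sd=5.655,
            ao_slope_mean=1.877,
            ao_slope_sd=1.86,
        ),
        normal=AlleleRegimeParams(
            fitness_mean=1.00,
            fitness_sd=0.25,
            segregation_mean=0.596,
            segregation_sd=0.085,
            instability_mean=0.23,
            instability_sd=0.468,
            ao_slope_mean=1.877,
            ao_slope_sd=1.86,
        ),
    ),
    "sca3": DiseaseConfig(
        name="sca3",
        pathogenic_threshold=51.0,
        ancestral_repeat=54.0,
        ancestral_ao=65.0,
        post_onset_birth_fraction=0.083,
        expanded=AlleleRegimeParams(
            fitness_mean=1.45,
            fitness_sd=0.25,
            segregation_mean=0.640,
            segregation_sd=0.085,
            instability_mean=1.23,
            instability_sd=5.126,
            ao_slope_mean=1.652,
            ao_slope_sd=1.729,
        ),
        normal=AlleleRegimeParams(
            fitness_mean=1.00,
            fitness_sd=0.25,
            segregation_mean=0.360,
            segregation_sd=0.085,
            instability_mean=0.00,
            instability_sd=0.468,  # imputed, borrowed from ATXN2
            ao_slope_mean=1.652,
            ao_slope_sd=1.729,
        ),
    ),
}


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> DiseaseConfig:
    """Return the packaged configuration for a disease label.

    Parameters
    ----------
    name
        Disease label, one of ``available_presets()`` (case-insensitive).
    """
    key = name.lower()
    if key not in _PRESETS:
        raise ConfigError(
            f"unknown disease preset {name!r}; available presets: "
            + ", ".join(available_presets())
        )
    return _PRESETS[key]


def validate_config(cfg: DiseaseConfig) -> DiseaseConfig:
    """Check every type invariant; return ``cfg`` unchanged if all hold.

    Raises
    ------
    ConfigError
        Listing every violated invariant with field name and value.
    """
    errs: list[str] = []
    errs += cfg.expanded.validation_errors("expanded.")
    errs += cfg.normal.validation_errors("normal.")
    if not cfg.ancestral_repeat >= cfg.pathogenic_threshold:
        errs.append(
            "ancestral_repeat must be >= pathogenic_threshold, got "
            f"ancestral_repeat={cfg.ancestral_repeat} < {cfg.pathogenic_threshold}"
        )
    if not (0.0 < cfg.initial_frequency < 1.0):
        errs.append(f"initial_frequency must be in (0,1), got {cfg.initial_frequency}")
    if not (0.0 <= cfg.post_onset_birth_fraction <= 1.0):
        errs.append(
            "post_onset_birth_fraction must be in [0,1], got "
            f"{cfg.post_onset_birth_fraction}"
        )
    lo, hi = cfg.reproductive_window
    if not lo < hi:
        errs.append(f"reproductive_window must have min_age < max_age, got ({lo}, {hi})")
    if not cfg.max_generations >= 1:
        errs.append(f"max_generations must be >= 1, got {cfg.max_generations}")
    if cfg.draw_regime not in ("parental", "offspring"):
        errs.append(f"draw_regime must be 'parental' or 'offspring', got {cfg.draw_regime!r}")
    if errs:
        raise ConfigError("; ".join(errs))
    return cfg


def config_to_dict(cfg: DiseaseConfig) -> dict:
    d = asdict(cfg)
    d["reproductive_window"] = list(cfg.reproductive_window)
    return d


def config_from_dict(d: dict) -> DiseaseConfig:
    d = dict(d)
    d["expanded"] = AlleleRegimeParams(**d["expanded"])
    d["normal"] = AlleleRegimeParams(**d["normal"])
    d["reproductive_window"] = tuple(d["reproductive_window"])
    return validate_config(DiseaseConfig(**d))


def save_config(cfg: DiseaseConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=2) + "\n")


def load_config(path: Union[str, Path]) -> DiseaseConfig:
    return config_from_dict(json.loads(Path(path).read_text()))
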