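# Methods

## Model

`cagsim` tracks one lineage descending from a single de novo CAG expansion
carrier. The state per generation is the population frequency `p` of the
tracked allele, its continuous repeat length, and the implied age at onset
(AO) for that length. Because expanded alleles are vanishingly rare and
fully dominant, homozygote and wild-type terms of the classical diploid
selection equation drop out, leaving the per-generation recursion

    p' = p · w · antcoeff · 2k

with relative carrier fitness `w`, segregation coefficient `k`, and the
anticipation coefficient `antcoeff` (1 while the allele is in the normal
repeat range). The model deliberately excludes de novo mutation influx,
genetic drift and gene flow: the recursion is a deterministic map given the
sampled coefficients, and all stochasticity enters through the parameter
draws.

Each generation four coefficients are drawn independently from untruncated
Gaussians with regime-specific means and SDs (see the preset tables in
`cagsim.params`): `w`, `k`, the repeat-length change per transmission Δ,
and the AO-reduction slope per added repeat. Then

1. repeat' = repeat + Δ,
2. AO' = AO − Δ · slope (a contraction raises the implied onset age),
3. the allele class (expanded vs normal) is re-evaluated against the
   pathogenic threshold, inclusively (≥ 34 repeats for *ATXN2*, ≥ 51 for
   *ATXN3*),
4. antcoeff is computed from AO' if the *transmitted* allele is expanded,
   else it is exactly 1,
5. the frequency updates through the recursion, clamped to [0, 1]: a
   non-positive product collapses to exactly 0 (elimination), a product
   ≥ 1 to exactly 1 (fixation).

The transmission draw comes from the regime the allele is in when
transmitted (the parent's class — instability is a property of the
transmitting meiosis), while the anticipation penalty applies to the class
of the allele the offspring receives. `DiseaseConfig.draw_regime =
"offspring"` switches the w/k draw to the post-instability class instead.

Fixation is absorbing for the frequency (pinned at 1) but repeat/AO
dynamics continue; if continuing expansion pushes AO to or below the start
of the reproductive window while expanded, the lineage is classified
extinct-after-fixation. Lineages reaching the 650-generation horizon with
0 < p < 1 persist; no underflow floor is imposed on small frequencies —
persisting lineages legitimately reach frequencies of order 1e-100 or
smaller, far above the smallest positive double.

## Anticipation coefficient

The fertility schedule (births/woman/year by single year of age) is
treated as a piecewise-linear density; its area over the reproductive
window (12–50 years) is normalised to 1. For a carrier with onset age AO,

    antcoeff = 0                                   if AO ≤ 12
    antcoeff = 1                                   if AO ≥ 50
    antcoeff = min(1, C(AO) + f_post)              otherwise

where `C` is the normalised cumulative fertility area from age 12 (exact
trapezoidal integration between tabulated ages) and `f_post` is the
fraction of children born after parental onset (0.08 for SCA2, 0.083 for
SCA3). **This closed form is a reconstruction**: the defining source for
the coefficient describes the area normalisation, the 0/1 boundary
behaviour and an additive post-onset birth percentage, but the exact
published expression was not available. The additive-then-clamp reading is
the simplest consistent one; the alternative multiplicative reading
(scaling age-specific rates by 1 + f_post) differs only near small
coefficients and was not adopted. The observed mean intervals between
births and parental onset (≈13–14 years) are treated purely as the
provenance of the 8 %/8.3 % figures, not as an AO offset.

The packaged default schedule is synthetic: a Gaussian-shaped curve on
integer ages 12–50 peaking at age 30 with spread 6 years, emulating the
shape of the EUROSTAT 2019 European female fertility curve (unimodal, peak
near 30, near-zero at the window edges). Users can substitute a real
single-year `age,rate` CSV. Fate statistics that hinge on when the
coefficient starts to bite (fixation counts and repeat lengths at
fixation) are the most sensitive to the schedule shape; the elimination
boundary (AO ≤ 12) is schedule-independent.

## Parameters

Preset values are literature meta-analysis means (SDs in parentheses):

| quantity | SCA2 expanded | SCA2 normal | SCA3 expanded | SCA3 normal |
|---|---|---|---|---|
| fitness w | 1.50 (0.25ᵃ) | 1.00 (0.25ᵃ) | 1.45 (0.25ᵃ) | 1.00 (0.25ᵃ) |
| segregation k | 0.404 (0.085ᵃ) | 0.596 (0.085ᵃ) | 0.640 (0.085) | 0.360 (0.085) |
| instability Δ (repeats) | 2.42 (5.655) | 0.23 (0.468) | 1.23 (5.126) | 0.00ᵃ (0.468ᵃ) |
| AO slope (y/repeat) | 1.877 (1.86) | — | 1.652 (1.729) | — |

ᵃ imputed values: the fitness SDs (0.25) and the SCA2 segregation SD are
imputations carried verbatim from the source tables; the normal-*ATXN3*
instability SD is borrowed from *ATXN2*. The sensitivity sweep
(`sensitivity_sweep`) re-runs ensembles under alternative fitness SDs for
both regimes jointly (optionally per regime).

The normal-allele rows have no AO slope of their own; the presets copy the
disease's expanded-regime slope into the normal regime so the implied AO
keeps tracking repeat length through contractions and re-expansions. Run
controls: initial frequency 1e-6, generation cap 650 (the horizon
corresponding to roughly 16,000 years at ~25 y/generation), ancestral
state 34 repeats / AO 55 y (SCA2) and 54 repeats / AO 65 y (SCA3) — the
mildest described ancestors. Repeat lengths are continuous reals
throughout: the instability parameters are mean per-transmission effects,
and lineage-average repeat lengths are not integers.

## Randomness and reproducibility

Per-lineage random streams are spawned as
`numpy.random.SeedSequence(master_seed).spawn(n)`; lineage *i* always
receives the *i*-th child, so ensembles are bit-reproducible, independent
of execution order, and prefix-stable (the first 1,000 lineages of a
4,000-lineage run equal the 1,000-lineage run at the same seed). Draws are
untruncated: a rare non-positive sampled `w` or `k` collapses the
frequency to 0 and counts as elimination — this is the only elimination
channel available to an allele in the normal range, and matches the
occasional low-repeat eliminations seen in ensembles.

## Deterministic oracles

With all SDs zeroed the engine follows the mean path and elimination
occurs at generation ceil((AO₀ − 12)/(Δ̄ · slopē)): generation 10 for the
SCA2 preset and 27 for SCA3. These closed forms, the log-space equality of
the simulated trajectory with the analytic product p₀·∏(wᵢ·antᵢ·2kᵢ), and
the exact 0/1 antcoeff boundaries are tested as exact oracles.

## Known limitations

* The antcoeff closed form is a reconstruction (above); fixation-related
  statistics are the most sensitive to it. The stochastic acceptance
  checks carry an explicit reconstruction slack, and several fate
  statistics (SCA3 elimination-generation median, fixation-generation
  medians, SCA3 repeat length at fixation, SCA3 persisting count) sit
  outside even that slack under the per-generation Gaussian sampling
  implemented here; the corresponding checks are left failing rather than
  tuned. Distributional signatures of the published ensembles (minimum
  fixation generations, elimination medians at the deterministic values)
  suggest the original implementation held some sampled coefficients
  constant within a lineage, but no documented variant reproduces the full
  published profile, so the contracted per-generation sampling is kept.
* The SCA3 persisting fraction exceeds 0.25 on seed-averaged ensembles but
  with a thin margin (≈0.256); single seeds can fall below it.
* The fertility schedule is contemporary; historical populations
  reproduced earlier, which would have relaxed selection against
  anticipation. Cohort effects, male/female schedule differences and
  fertility projection are out of scope.
* The model is a frequency recursion, not an individual-based pedigree
  simulation: no drift, no de novo mutation influx, no gene flow, and no
  dosage effects in homozygotes.
* The synthetic schedule emulates only the qualitative EUROSTAT 2019
  shape; passing tests demonstrate internal consistency of the model, not
  calibration to any specific real population's fertility table.

## Problem sizes

The packaged study design is 1,000 lineages per ensemble and a
650-generation horizon; the test suite and the acceptance script run five
independent 1,000-lineage ensembles per disease (≈15 s total on one core),
the full published scale.
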