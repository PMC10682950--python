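import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagsim import (
    GenerationDraw,
    LineageState,
    anticipation_coefficient,
    classify,
    draw_generation_params,
    frequency_update,
    make_synthetic_schedule,
    preset,
    simulate_lineage,
    step_lineage,
)
from cagsim.lineage import ELIMINATED, FIXED_HELD, FIXED_THEN_EXTINCT, PERSISTING


class TestFrequencyUpdate:
    def test_printed_recursion_example(self):
        # one SCA2 ancestor transmission at mean parameters, antcoeff 1
        assert frequency_update(1e-6, 1.5, 1.0, 0.404) == pytest.approx(1.212e-6)

    def test_neutral_mendelian_identity(self):
        for p in (1e-6, 0.2, 0.97):
            assert frequency_update(p, 1.0, 1.0, 0.5) == p

    def test_zero_antcoeff_annihilates(self):
        assert frequency_update(0.3, 1.5, 0.0, 0.64) == 0.0

    def test_clamped_at_fixation(self):
        assert frequency_update(0.9, 1.45, 1.0, 0.64) == 1.0

    def test_negative_factor_clamps_to_zero(self):
        assert frequency_update(0.5, -0.1, 1.0, 0.5) == 0.0


class TestGenerationDraws:
    def test_degenerate_sds_return_means(self, sca2):
        rp = preset("sca2").with_zero_sds().expanded
        draw = draw_generation_params(np.random.default_rng(0), rp)
        assert draw == GenerationDraw(w=1.50, k=0.404, delta_repeats=2.42, ao_slope=1.877)

    def test_stream_contract(self, sca2):
        rng = np.random.default_rng(42)
        d1 = draw_generation_params(rng, sca2.expanded)
        d2 = draw_generation_params(rng, sca2.expanded)
        assert d1 != d2
        rng2 = np.random.default_rng(42)
        assert draw_generation_params(rng2, sca2.expanded) == d1

    def test_sample_moments_recover_parameters(self, sca2):
        """1e5 instability draws recover the configured mean and SD
        within three standard errors."""
        rng = np.random.default_rng(7)
        n = 100_000
        deltas = np.array(
            [draw_generation_params(rng, sca2.expanded).delta_repeats for _ in range(n)]
        )
        se_mean = 5.655 / math.sqrt(n)
        assert abs(deltas.mean() - 2.42) < 3 * se_mean
        se_sd = 5.655 / math.sqrt(2 * (n - 1))
        assert abs(deltas.std(ddof=1) - 5.655) < 3 * se_sd


class TestStepLineage:
    def test_deterministic_sca2_step(self, schedule):
        cfg = preset("sca2").with_zero_sds()
        state = LineageState(0, 1e-6, 34.0, 55.0, "expanded")
        draw = draw_generation_params(np.random.default_rng(0), cfg.expanded)
        nxt = step_lineage(state, draw, cfg, schedule)
        assert nxt.repeat_length == pytest.approx(36.42)
        assert nxt.ao == pytest.approx(55 - 2.42 * 1.877)  # 50.45766 > 50: antcoeff 1
        assert nxt.regime == "expanded"
        assert nxt.frequency == pytest.approx(1e-6 * 1.5 * 1.0 * 0.808)

    def test_deterministic_sca3_normal_step(self, schedule):
        cfg = preset("sca3").with_zero_sds()
        state = LineageState(3, 1e-4, 48.0, 70.0, "normal")
        draw = draw_generation_params(np.random.default_rng(0), cfg.normal)
        nxt = step_lineage(state, draw, cfg, schedule)
        assert nxt.repeat_length == 48.0  # normal ATXN3 instability mean 0
        assert nxt.frequency == pytest.approx(1e-4 * 1.0 * 1.0 * 2 * 0.36)

    def test_contraction_reenters_normal_regime(self, schedule, sca2):
        state = LineageState(1, 1e-6, 35.0, 50.0, "expanded")
        draw = GenerationDraw(w=1.5, k=0.404, delta_repeats=-4.0, ao_slope=1.877)
        nxt = step_lineage(state, draw, cfg=sca2, s=schedule)
        assert nxt.repeat_length == pytest.approx(31.0)
        assert nxt.regime == "normal"
        # contraction raises the implied onset age
        assert nxt.ao > state.ao

    def test_fixed_state_pins_frequency(self, schedule, sca3):
        state = LineageState(10, 1.0, 60.0, 40.0, "expanded", fixed=True,
                             fixation_generation=10)
        draw = GenerationDraw(w=0.5, k=0.1, delta_repeats=2.0, ao_slope=1.652)
        nxt = step_lineage(state, draw, cfg=sca3, s=schedule)
        assert nxt.frequency == 1.0
        assert nxt.fixed
        assert nxt.repeat_length == pytest.approx(62.0)


class TestSimulateLineage:
    def test_deterministic_sca2_eliminated_at_10(self, schedule):
        """With SDs zeroed the SCA2 ancestor line dies in exactly 10
        generations: the onset age crosses 12 y after ceil(43/4.54234)
        transmissions."""
        cfg = preset("sca2").with_zero_sds()
        out = simulate_lineage(cfg, schedule, 0)
        assert out.status == ELIMINATED
        assert out.terminal_generation == 10

    def test_deterministic_sca3_eliminated_at_27(self, schedule):
        cfg = preset("sca3").with_zero_sds()
        out = simulate_lineage(cfg, schedule, 0)
        assert out.status == ELIMINATED
        assert out.terminal_generation == 27

    def test_deterministic_sca2_never_fixes(self, schedule):
        cfg = preset("sca2").with_zero_sds()
        out = simulate_lineage(cfg, schedule, 0)
        assert out.fixation_generation is None
        assert max(rec.frequency for rec in out.trajectory) < 1e-4

    @settings(deadline=None, max_examples=40)
    @given(
        ao0=st.floats(min_value=20.0, max_value=80.0),
        instability=st.floats(min_value=0.5, max_value=6.0),
        slope=st.floats(min_value=0.5, max_value=3.0),
    )
    def test_zero_sd_engine_matches_closed_form(self, schedule, ao0, instability, slope):
        """Deterministic elimination generation equals
        ceil((AO0 - 12) / (instability x slope)) for arbitrary regimes."""
        cfg = preset("sca2").with_zero_sds()
        cfg = dataclasses.replace(
            cfg,
            ancestral_ao=ao0,
            expanded=dataclasses.replace(
                cfg.expanded, instability_mean=instability, ao_slope_mean=slope,
                fitness_mean=1.0, segregation_mean=0.4,
            ),
        )
        expected = math.ceil((ao0 - 12.0) / (instability * slope))
        out = simulate_lineage(cfg, schedule, 0)
        if expected <= cfg.max_generations:
            assert out.status == ELIMINATED
            assert out.terminal_generation == expected

    def test_increasing_instability_never_delays_elimination(self, schedule):
        cfg0 = preset("sca3").with_zero_sds()
        gens = []
        for inst in (0.5, 1.0, 1.23, 2.0, 4.0):
            cfg = dataclasses.replace(
                cfg0, expanded=dataclasses.replace(cfg0.expanded, instability_mean=inst)
            )
            gens.append(simulate_lineage(cfg, schedule, 0).terminal_generation)
        assert gens == sorted(gens, reverse=True)

    def test_trajectory_matches_analytic_product(self, sca3):
        """Replaying the draw stream, the frequency at every generation
        equals p0 * prod(w_i * antcoeff_i * 2 k_i) to 1e-12 in log space."""
        schedule = make_synthetic_schedule()
        cfg = dataclasses.replace(sca3, post_onset_birth_fraction=0.0)
        seed = np.random.SeedSequence(2024)
        out = simulate_lineage(cfg, schedule, seed)
        # independent replay of the same stream
        rng = np.random.default_rng(np.random.SeedSequence(2024))
        log_p = math.log(cfg.initial_frequency)
        for prev, rec in zip(out.trajectory, out.trajectory[1:]):
            rp = cfg.expanded if prev.regime == "expanded" else cfg.normal
            draw = draw_generation_params(rng, rp)
            ant = (
                anticipation_coefficient(schedule, rec.ao, 0.0)
                if rec.regime == "expanded"
                else 1.0
            )
            factor = draw.w * ant * 2 * draw.k
            if factor <= 0 or rec.frequency in (0.0, 1.0):
                break
            log_p += math.log(factor)
            assert math.log(rec.frequency) == pytest.approx(log_p, abs=1e-12)

    def test_frequency_bounded_in_unit_interval(self, schedule, sca2, sca3):
        for cfg, seed in ((sca2, 5), (sca3, 6), (sca2, 7), (sca3, 8)):
            out = simulate_lineage(cfg, schedule, seed)
            assert all(0.0 <= rec.frequency <= 1.0 for rec in out.trajectory)

    def test_bitwise_reproducibility(self, schedule, sca3):
        a = simulate_lineage(sca3, schedule, 123)
        b = simulate_lineage(sca3, schedule, 123)
        assert a.trajectory == b.trajectory
        assert a.status == b.status

    def test_post_fixation_extinction_classified(self, schedule):
        """A fixed lineage whose continuing expansion pushes onset below the
        reproductive window is extinct after fixation."""
        cfg = preset("sca3")
        found = None
        for seed in range(300):
            out = simulate_lineage(cfg, schedule, seed)
            if out.status == FIXED_THEN_EXTINCT:
                found = out
                break
        assert found is not None
        assert found.fixation_generation is not None
        assert found.terminal_generation >= found.fixation_generation
        last = found.trajectory[-1]
        assert last.regime == "expanded" and last.ao <= 12.0


class TestClassify:
    def test_partition_rules(self):
        assert classify(frequency=0.0, fixed=False, extinct_after_fixation=False,
                        at_horizon=False) == ELIMINATED
        assert classify(frequency=1.0, fixed=True, extinct_after_fixation=True,
                        at_horizon=False) == FIXED_THEN_EXTINCT
        assert classify(frequency=1.0, fixed=True, extinct_after_fixation=False,
                        at_horizon=True) == FIXED_HELD
        assert classify(frequency=0.3, fixed=False, extinct_after_fixation=False,
                        at_horizon=True) == PERSISTING

    def test_non_terminal_rejected(self):
        with pytest.raises(ValueError):
            classify(frequency=0.5, fixed=False, extinct_after_fixation=False,
                     at_horizon=False)
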