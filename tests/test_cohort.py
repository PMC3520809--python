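"""Synthetic cohort generator: attrition, determinism, recovery, coupling."""

import numpy as np
import pandas as pd
import pytest

from cardiotox_utc import GeneratorConfig, generate_cohort
from cardiotox_utc.cohort import (
    AnimalState,
    _expected_value,
    frames_per_cycle,
    generate_ibs_trace,
    generate_mmode,
    substream,
)
from cardiotox_utc.config import STUDY_GROUP_SIZES, STUDY_SACRIFICES
from cardiotox_utc.errors import ConfigurationError, InputError, SamplingError
from conftest import SEED, small_config


class TestConfigValidation:
    def test_increasing_group_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(group_sizes=[60, 23, 25, 14, 9, 7])

    def test_baseline_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_baseline=50)

    def test_negative_spread_rejected(self):
        cfg = GeneratorConfig().model_dump()
        cfg["group_sds"]["mcv"][8.0] = -1.0
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**cfg)

    def test_shortening_fraction_outside_unit_interval_rejected(self):
        cfg = GeneratorConfig().model_dump()
        cfg["group_means"]["sf_pct"][16.0] = 120.0
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**cfg)

    def test_infeasible_sacrifice_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(small_config(sacrifice_schedule={0.0: 2, 16.0: 11}), seed=0)


class TestAttrition:
    def test_examined_counts_reproduce_study_n_row(self, default_cohort):
        assert default_cohort.group_sizes() == STUDY_GROUP_SIZES

    def test_sacrifice_schedule_reproduced(self, default_cohort):
        counts = default_cohort.hearts.groupby("dose_mg_per_kg").size().to_dict()
        assert counts == STUDY_SACRIFICES

    def test_no_measurements_after_exit(self, default_cohort):
        for a in default_cohort.animals:
            sub = default_cohort.exams[default_cohort.exams.animal_id == a.animal_id]
            if len(sub):
                assert sub.dose_mg_per_kg.max() <= a.alive_through_dose
            if a.sacrificed_at is not None:
                assert not (sub.dose_mg_per_kg > a.sacrificed_at).any()

    def test_deaths_remove_highest_injury_first(self, default_cohort):
        """Animals lost to follow-up (not sacrificed) after baseline carry
        more latent injury than protocol completers."""
        dosed = [a for a in default_cohort.animals if a.sacrificed_at != 0.0]
        early_dead = [
            a.latent_injury
            for a in dosed
            if a.sacrificed_at is None and a.alive_through_dose == 0.0
        ]
        others = [
            a.latent_injury for a in dosed if a.alive_through_dose > 0.0
        ]
        assert early_dead and others
        assert min(early_dead) > max(others)


class TestDeterminism:
    def test_same_seed_identical_different_seed_differs(self, default_config):
        a = generate_cohort(default_config, seed=42)
        b = generate_cohort(default_config, seed=42)
        pd.testing.assert_frame_equal(a.exams, b.exams)
        pd.testing.assert_frame_equal(a.hearts, b.hearts)
        c = generate_cohort(default_config, seed=43)
        assert not a.exams["cc_ibs"].equals(c.exams["cc_ibs"])

    def test_named_substreams_are_independent(self):
        x = substream(1, "values").standard_normal(4)
        y = substream(1, "values").standard_normal(4)
        z = substream(1, "collagen").standard_normal(4)
        assert np.array_equal(x, y)
        assert not np.array_equal(x, z)


class TestZeroNoiseRecovery:
    def test_every_baseline_record_equals_configured_mean(self, zero_noise_cohort):
        base = zero_noise_cohort.exams.query("dose_mg_per_kg == 0")
        assert np.allclose(base.cc_ibs, 1.1)
        assert np.allclose(base.mcv, 11.02)

    def test_group_means_exact_at_all_doses(self, zero_noise_cohort):
        cfg = zero_noise_cohort.config
        for dose, grp in zero_noise_cohort.exams.groupby("dose_mg_per_kg"):
            for var in ("cc_ibs", "mcv", "sf_pct"):
                assert grp[var].mean() == pytest.approx(
                    cfg.mean(var, dose), abs=1e-12
                ), (var, dose)

    def test_collagen_truth_exact(self, zero_noise_cohort):
        cfg = zero_noise_cohort.config
        for dose, grp in zero_noise_cohort.hearts.groupby("dose_mg_per_kg"):
            assert grp.true_collagen_pct.mean() == pytest.approx(
                cfg.mean("collagen_pct", dose), abs=1e-12
            )


class TestNoisyRecovery:
    def test_group_means_within_monte_carlo_error(self, default_cohort):
        """Default-noise group means stay within 3 SDs/sqrt(n) of the
        configured means (the generator's sampling contract)."""
        cfg = default_cohort.config
        for dose, grp in default_cohort.exams.groupby("dose_mg_per_kg"):
            for var in ("cc_ibs", "mcv", "sf_pct"):
                se = cfg.sd(var, dose) / np.sqrt(len(grp))
                assert abs(grp[var].mean() - cfg.mean(var, dose)) < 3 * se + 1e-9

    def test_group_spreads_near_configured(self, default_cohort):
        cfg = default_cohort.config
        base = default_cohort.exams.query("dose_mg_per_kg == 0")
        assert cfg.sd("cc_ibs", 0.0) * 0.6 < base.cc_ibs.std(ddof=1) < cfg.sd(
            "cc_ibs", 0.0
        ) * 1.5


class TestCouplingStructure:
    def test_expected_trajectories_monotone_for_monotone_means(self):
        """With monotone configured means, higher latent injury means a
        steeper expected CC-IBS rise and MCV fall at every dose."""
        cfg = GeneratorConfig()
        cfg.group_means["cc_ibs"] = {0.0: 1.1, 8.0: 1.2, 10.0: 1.25, 12.0: 1.3, 14.0: 1.35, 16.0: 1.4}
        cfg.group_means["mcv"] = {0.0: 11.0, 8.0: 9.5, 10.0: 9.0, 12.0: 8.5, 14.0: 8.0, 16.0: 7.5}
        for injury in (0.5, 1.0, 1.8):
            cc = [_expected_value(cfg, "cc_ibs", d, injury) for d in cfg.dose_schedule]
            mcv = [_expected_value(cfg, "mcv", d, injury) for d in cfg.dose_schedule]
            assert all(b >= a - 1e-12 for a, b in zip(cc, cc[1:]))
            assert all(b <= a + 1e-12 for a, b in zip(mcv, mcv[1:]))
        # and the injury ordering is respected at a fixed dose
        assert _expected_value(cfg, "cc_ibs", 16.0, 1.8) > _expected_value(
            cfg, "cc_ibs", 16.0, 0.5
        )

    def test_zero_injury_animal_has_flat_expected_trajectory(self):
        """An animal with zero latent injury keeps its baseline expectation
        at every dose, whatever the group dose effect."""
        cfg = GeneratorConfig()
        for var in ("cc_ibs", "mcv", "sf_pct"):
            vals = [_expected_value(cfg, var, d, 0.0) for d in cfg.dose_schedule]
            assert np.allclose(vals, cfg.mean(var, 0.0))

    def test_constant_mean_config_gives_dose_independent_expectations(self):
        cfg = GeneratorConfig()
        cfg.group_means["sf_pct"] = {d: 50.0 for d in cfg.dose_schedule}
        vals = [_expected_value(cfg, "sf_pct", d, 1.7) for d in cfg.dose_schedule]
        assert np.allclose(vals, 50.0)


class TestTraceAndMModeFixtures:
    def test_frames_per_cycle_arithmetic(self, default_config):
        assert frames_per_cycle(default_config) == pytest.approx(20.0)

    def test_low_frame_rate_raises_sampling_error(self):
        cfg = GeneratorConfig(frame_rate_hz=15.0)  # 3 frames/cycle at 300 bpm
        a = AnimalState(animal_id=1, latent_injury=1.0, alive_through_dose=16.0)
        with pytest.raises(SamplingError):
            generate_ibs_trace(a, 0.0, cfg)

    def test_trace_requires_alive_animal_and_scheduled_dose(self, default_config):
        a = AnimalState(animal_id=1, latent_injury=1.0, alive_through_dose=8.0)
        with pytest.raises(InputError):
            generate_ibs_trace(a, 12.0, default_config)
        with pytest.raises(InputError):
            generate_ibs_trace(a, 7.0, default_config)

    def test_mmode_zero_noise_dimensions(self, default_config):
        cfg = default_config.zero_noise()
        a = AnimalState(animal_id=1, latent_injury=1.0, alive_through_dose=16.0)
        cycles = generate_mmode(a, 0.0, cfg, sf_pct=50.0, lvedd_cm=0.8)
        assert len(cycles) == 3
        assert all(c.lvesd_cm == pytest.approx(0.4) for c in cycles)
        cycles16 = generate_mmode(a, 16.0, cfg, sf_pct=33.4, lvedd_cm=0.8)
        assert cycles16[0].lvesd_cm == pytest.approx(0.5328)

    def test_mmode_rejects_unphysiological_target(self, default_config):
        a = AnimalState(animal_id=1, latent_injury=1.0, alive_through_dose=16.0)
        with pytest.raises(ConfigurationError):
            generate_mmode(a, 0.0, default_config, sf_pct=104.0)
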