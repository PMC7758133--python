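"""Synthetic cohort generator: determinism, calibration, mechanism."""

from dataclasses import replace

import numpy as np
import pytest

from retscreen.cohort import Modality
from retscreen.grading import PatientCategory
from retscreen.simulate import run_two_round_study
from retscreen.synthcohort import (
    GraderParams,
    SyntheticConfig,
    expected_round1_prevalence,
    expected_round1_sensitivity,
    expected_round1_specificity,
    expected_stdr_mass,
    generate_cohort,
    paper_default_config,
    spectrum_shift_experiment,
)


class TestDeterminism:
    def test_bit_identical_output_for_identical_config(self, default_config):
        cfg = replace(default_config, n_patients=500)
        rec_a, log_a = generate_cohort(cfg)
        rec_b, log_b = generate_cohort(cfg)
        assert rec_a == rec_b
        assert log_a.equals(log_b)

    def test_growing_the_cohort_preserves_earlier_patients(self, default_config):
        small, log_small = generate_cohort(replace(default_config, n_patients=150))
        large, log_large = generate_cohort(replace(default_config, n_patients=300))
        # ids differ only by zero-padding width; compare substance
        for a, b in zip(small, large[:150]):
            assert a.round1 == b.round1
            assert a.round2 == b.round2
            assert a.latent_difficulty == b.latent_difficulty
        assert log_small.drop(columns="patient_id").equals(
            log_large.iloc[:150].drop(columns="patient_id")
        )

    def test_different_seeds_differ(self, default_config):
        rec_a, _ = generate_cohort(replace(default_config, n_patients=200, seed=1))
        rec_b, _ = generate_cohort(replace(default_config, n_patients=200, seed=2))
        assert rec_a != rec_b


class TestConfigValidation:
    def test_bad_probability_vectors_rejected_before_any_draw(self, default_config):
        bad = list(default_config.baseline_probs)
        bad[0] += 0.01
        with pytest.raises(ValueError):
            replace(default_config, baseline_probs=tuple(bad))
        tr = [list(r) for r in default_config.transition]
        tr[2][2] += 1e-6
        with pytest.raises(ValueError):
            replace(default_config, transition=tuple(tuple(r) for r in tr))

    def test_grader_params_bounds(self):
        with pytest.raises(ValueError):
            GraderParams(1.2, 1.0, 0.99, 1.0, 0.1)
        with pytest.raises(ValueError):
            GraderParams(1.0, 1.0, 0.99, -1.0, 0.1)


class TestCalibration:
    def test_baseline_case_mix_matches_target(self, synthetic_cohort, default_config):
        records, log = synthetic_cohort
        frac_no_dr = (log.true_cat_r1 == PatientCategory.NO_DR.value).mean()
        assert frac_no_dr * 100 == pytest.approx(72.36, abs=1.5)
        assert expected_round1_prevalence(default_config) == pytest.approx(
            0.1227, abs=0.0005
        )

    def test_expected_grader_operating_points(self, default_config):
        assert expected_round1_sensitivity(
            default_config, Modality.DL
        ) == pytest.approx(0.95, abs=0.005)
        assert expected_round1_sensitivity(
            default_config, Modality.HG
        ) == pytest.approx(0.74, abs=0.005)
        for arm in (Modality.DL, Modality.HG):
            assert 0.97 < expected_round1_specificity(default_config, arm) < 0.995

    def test_transition_rate_matches_analytic_mass(self, default_config):
        """On a large cohort the realised 2-year STDR rate from moderate
        NPDR matches the transition row's STDR mass (the analytic oracle)."""
        cfg = replace(default_config, n_patients=200_000, seed=3)
        _, log = generate_cohort(cfg)
        moderate = log[log.true_cat_r1 == PatientCategory.MODERATE_NO_DME.value]
        realised = moderate.incident_stdr.mean()
        analytic = expected_stdr_mass(cfg, PatientCategory.MODERATE_NO_DME)
        assert realised == pytest.approx(analytic, abs=0.01)
        assert analytic == pytest.approx(0.2526, abs=1e-9)

    def test_perfect_screener_makes_no_errors(self, default_config):
        perfect = GraderParams(
            base_sens_dme=1.0,
            base_sens_sevpdr=1.0,
            base_spec=1.0,
            fp_moderate_boost=1.0,
            difficulty_weight=0.0,
        )
        cfg = replace(
            default_config,
            n_patients=2000,
            graders={Modality.DL: perfect, Modality.HG: perfect},
            ungradable_rate=0.0,
            seed=9,
        )
        records, _ = generate_cohort(cfg)
        for arm in (Modality.DL, Modality.HG):
            res = run_two_round_study(records, arm)
            assert res.round1.contingency.fp == res.round1.contingency.fn == 0
            assert res.round2.contingency.fp == res.round2.contingency.fn == 0


class TestSpectrumShift:
    def test_difficulty_weight_widens_the_sensitivity_drop(self, default_config):
        """A 3-point sweep of the HG difficulty weight on large fixed-seed
        cohorts: the round-1 -> round-2 sensitivity drop weakly increases."""
        drops = []
        for w in (0.0, 0.24, 0.48):
            hg = replace(default_config.graders[Modality.HG], difficulty_weight=w)
            cfg = replace(
                default_config,
                n_patients=50_000,
                graders={
                    Modality.DL: default_config.graders[Modality.DL],
                    Modality.HG: hg,
                },
                seed=13,
            )
            records, _ = generate_cohort(cfg)
            res = run_two_round_study(records, Modality.HG)
            ct1, ct2 = res.round1.contingency, res.round2.contingency
            drops.append(
                ct1.tp / ct1.disease_positive - ct2.tp / ct2.disease_positive
            )
        assert drops[0] < drops[1] < drops[2]

    def test_round2_prevalence_falls_under_defaults(self, default_config):
        out = spectrum_shift_experiment(default_config, n_reps=8, seed=2)
        for summary in out.values():
            assert summary.prev_r2 < summary.prev_r1

    def test_experiment_needs_replicates(self, default_config):
        with pytest.raises(ValueError):
            spectrum_shift_experiment(default_config, n_reps=1, seed=0)
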