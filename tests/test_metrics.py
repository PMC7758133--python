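"""Contingency metrics, Wald intervals, chi-squared, stratified summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retscreen.cohort import Modality
from retscreen.grading import (
    DRSeverity,
    EyeAssessment,
    GradingError,
    PatientAssessment,
    PatientCategory,
    StdrSubtype,
)
from retscreen.cohort import ModalityGradeSet, PatientRecord
from retscreen.metrics import (
    ContingencyTable,
    UndefinedMetricError,
    accuracy,
    chi2_2x2,
    compare_rounds,
    eye_level_contingency,
    metric_from_table,
    moderate_no_dme_fraction,
    npv,
    ppv,
    sample_size,
    sensitivity,
    specificity,
    stdr_breakdown,
    wald_ci,
)

DL_ROUND1 = ContingencyTable(tp=669, fp=102, tn=4932, fn=35)


class TestBasicMetrics:
    def test_sensitivity_and_ppv_on_published_counts(self):
        assert sensitivity(DL_ROUND1).estimate == pytest.approx(95.03, abs=0.005)
        assert ppv(DL_ROUND1).estimate == pytest.approx(86.77, abs=0.005)

    def test_no_disease_present(self):
        ct = ContingencyTable(tp=0, fp=0, tn=10, fn=0)
        assert specificity(ct).estimate == 100.0
        with pytest.raises(UndefinedMetricError):
            sensitivity(ct)

    def test_counts_must_be_non_negative(self):
        with pytest.raises(ValueError):
            ContingencyTable(tp=-1, fp=0, tn=0, fn=0)

    @given(
        tp=st.integers(0, 5000),
        fp=st.integers(0, 5000),
        tn=st.integers(0, 5000),
        fn=st.integers(0, 5000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_rational_identities(self, tp, fp, tn, fn):
        """sens*(tp+fn) == 100*tp and the prevalence-weighted accuracy
        identity hold exactly (up to float round-off)."""
        ct = ContingencyTable(tp=tp, fp=fp, tn=tn, fn=fn)
        if tp + fn:
            assert sensitivity(ct).estimate * (tp + fn) == pytest.approx(
                100 * tp, rel=1e-12
            )
        if (tp + fn) and (tn + fp):
            prev = (tp + fn) / ct.n
            lhs = accuracy(ct).estimate
            rhs = sensitivity(ct).estimate * prev + specificity(ct).estimate * (
                1 - prev
            )
            assert lhs == pytest.approx(rhs, rel=1e-12)


class TestWaldCI:
    @pytest.mark.parametrize(
        "successes, n, low, high",
        [
            (669, 704, 93.42, 96.63),
            (519, 704, 70.47, 76.97),
            (10, 10, 100.00, 100.00),  # degenerate proportion clips at 100
            (0, 10, 0.00, None),
        ],
    )
    def test_bounds(self, successes, n, low, high):
        lo, hi = wald_ci(successes, n)
        assert lo == pytest.approx(low, abs=0.005)
        if high is not None:
            assert hi == pytest.approx(high, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(UndefinedMetricError):
            wald_ci(0, 0)
        with pytest.raises(ValueError):
            wald_ci(5, 4)

    @given(
        successes=st.integers(0, 1000),
        n=st.integers(1, 1000),
        level=st.sampled_from([0.8, 0.9, 0.95, 0.99]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_interval_brackets_estimate_within_bounds(self, successes, n, level):
        if successes > n:
            successes = n
        lo, hi = wald_ci(successes, n, level)
        p = 100 * successes / n
        assert 0 <= lo <= p <= hi <= 100


def _chi2_oracle(table):
    """Textbook Pearson statistic: sum over cells of (O - E)^2 / E."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestChi2:
    def test_matches_expected_count_oracle_on_random_tables(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 2000, size=4)
            stat, _ = chi2_2x2(a, b, c, d)
            assert stat == pytest.approx(_chi2_oracle([[a, b], [c, d]]), abs=1e-9)

    def test_published_sensitivity_comparison(self):
        _, p = chi2_2x2(669, 35, 190, 21)
        assert round(p, 3) == 0.008

    def test_identical_proportions(self):
        stat, p = chi2_2x2(10, 10, 10, 10)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)


class TestCompareRounds:
    def test_sensitivity_drop_between_screenings(self):
        ct2 = ContingencyTable(tp=190, fp=84, tn=3853, fn=21)
        comp = compare_rounds("sensitivity", DL_ROUND1, ct2)
        assert comp.difference == pytest.approx(-4.98, abs=0.005)
        assert round(comp.p, 3) == 0.008

    def test_identical_tables(self):
        comp = compare_rounds("accuracy", DL_ROUND1, DL_ROUND1)
        assert comp.difference == 0.0
        assert comp.p == pytest.approx(1.0)

    def test_unknown_metric(self):
        with pytest.raises(KeyError):
            metric_from_table("f1", DL_ROUND1)


class TestBreakdowns:
    def test_single_dme_case(self):
        out = stdr_breakdown([PatientCategory.DME])
        assert out[StdrSubtype.DME] == 100.0
        assert out[StdrSubtype.SEVERE_PDR] == 0.0

    def test_rejects_non_stdr_member_and_empty(self):
        with pytest.raises(GradingError):
            stdr_breakdown([PatientCategory.NO_DR])
        with pytest.raises(UndefinedMetricError):
            stdr_breakdown([])

    def test_moderate_fraction(self):
        cats = [PatientCategory.MODERATE_NO_DME] * 13 + [PatientCategory.NO_DR] * 58
        assert moderate_no_dme_fraction(cats) == pytest.approx(100 * 13 / 71)
        with pytest.raises(GradingError):
            moderate_no_dme_fraction([PatientCategory.DME])


def _record(pid, ref, mod):
    grades = ModalityGradeSet(reference=ref, dl=mod, hg=mod)
    return PatientRecord(patient_id=pid, round1=grades)


class TestEyeLevel:
    def test_one_patient_two_gradable_eyes(self):
        pa = PatientAssessment(
            EyeAssessment(DRSeverity.SEVERE_NPDR, False),
            EyeAssessment(DRSeverity.NO_DR, False),
        )
        ct = eye_level_contingency([_record("p1", pa, pa)], Modality.DL, 1)
        assert ct.n == 2
        assert (ct.tp, ct.fp, ct.fn) == (1, 0, 0)

    def test_perfect_screener_has_no_errors(self):
        pas = [
            PatientAssessment(
                EyeAssessment(DRSeverity.PDR, True), EyeAssessment.ungradable()
            ),
            PatientAssessment(
                EyeAssessment(DRSeverity.MILD_NPDR, False),
                EyeAssessment(DRSeverity.NO_DR, False),
            ),
        ]
        records = [_record(f"p{i}", pa, pa) for i, pa in enumerate(pas)]
        ct = eye_level_contingency(records, Modality.HG, 1)
        assert ct.fp == ct.fn == 0
        assert ct.n == 3  # the ungradable eye is skipped


class TestSampleSize:
    def test_relative_margin_formula(self):
        # a ~6.5% prevalence with 10% relative margin needs ~5.5k patients
        assert sample_size(0.065, 0.10, 0.05) == 5526
        assert sample_size(0.5, 0.10, 0.05) == 385

    def test_monotone_in_margin(self):
        sizes = [sample_size(0.065, m) for m in (0.20, 0.10, 0.05, 0.02)]
        assert sizes == sorted(sizes)
        assert len(set(sizes)) == len(sizes)

    def test_domain(self):
        with pytest.raises(ValueError):
            sample_size(0.0)
        with pytest.raises(ValueError):
            sample_size(1.2)
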