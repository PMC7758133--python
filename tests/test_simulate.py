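"""Two-round referral simulation: screening, referral, cohort rebuilding."""

from dataclasses import replace

import pytest

from retscreen.cohort import Modality, ModalityGradeSet, PatientRecord
from retscreen.grading import (
    DRSeverity,
    EyeAssessment,
    PatientAssessment,
)
from retscreen.simulate import (
    SimulationError,
    build_followup_cohort,
    confirm_and_refer,
    run_two_round_study,
    screen_round,
)
from retscreen.synthcohort import generate_cohort


def _pa(sev="NO_DR", dme=False):
    return PatientAssessment(
        EyeAssessment(DRSeverity[sev], dme), EyeAssessment(DRSeverity.NO_DR, False)
    )


def _patient(pid, ref, dl=None, hg=None, round2=None):
    return PatientRecord(
        patient_id=pid,
        round1=ModalityGradeSet(reference=ref, dl=dl or ref, hg=hg or ref),
        round2=round2,
    )


STDR = _pa("SEVERE_NPDR")
HEALTHY = _pa("NO_DR")
UNGRADABLE = PatientAssessment(EyeAssessment.ungradable(), EyeAssessment.ungradable())


class TestScreenRound:
    def test_perfect_screener_has_no_errors(self):
        cohort = [_patient("a", STDR), _patient("b", HEALTHY), _patient("c", HEALTHY)]
        out = screen_round(cohort, Modality.DL, 1)
        ct = out.contingency
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (1, 0, 2, 0)

    def test_contingency_covers_exactly_the_doubly_gradable(self):
        cohort = [
            _patient("a", STDR, dl=HEALTHY),          # false negative
            _patient("b", HEALTHY, dl=STDR),          # false positive
            _patient("c", UNGRADABLE, dl=HEALTHY),    # reference ungradable
            _patient("d", HEALTHY, dl=UNGRADABLE),    # modality ungradable
        ]
        out = screen_round(cohort, Modality.DL, 1)
        assert out.contingency.n == 2
        assert out.excluded["reference_ungradable"] == {"c"}
        assert out.excluded["dl_ungradable"] == {"d"}

    def test_empty_cohort_rejected(self):
        with pytest.raises(SimulationError):
            screen_round([], Modality.DL, 1)

    def test_reference_is_not_an_arm(self):
        with pytest.raises(ValueError):
            screen_round([_patient("a", HEALTHY)], Modality.REFERENCE, 1)


class TestReferral:
    def test_only_confirmed_stdr_is_referred(self):
        cohort = [
            _patient("tp", STDR),
            _patient("fp", HEALTHY, dl=STDR),
            _patient("tn", HEALTHY),
        ]
        out = screen_round(cohort, Modality.DL, 1)
        referred = confirm_and_refer(out)
        assert referred == {"tp"}  # the false positive stays in the program

    def test_no_positives_no_referrals(self):
        out = screen_round([_patient("a", HEALTHY)], Modality.DL, 1)
        assert confirm_and_refer(out) == frozenset()

    def test_referred_must_belong_to_cohort(self):
        with pytest.raises(SimulationError):
            build_followup_cohort(
                [_patient("a", HEALTHY)], frozenset({"ghost"}), Modality.DL
            )


class TestFollowupCohort:
    def test_zero_referrals_zero_dropout_identity(self):
        r2 = ModalityGradeSet(reference=HEALTHY, dl=HEALTHY, hg=HEALTHY)
        cohort = [_patient(f"p{i}", HEALTHY, round2=r2) for i in range(4)]
        survivors, dropouts = build_followup_cohort(cohort, frozenset(), Modality.DL)
        assert survivors == cohort
        assert dropouts == frozenset()

    def test_dropout_reasons(self):
        good = ModalityGradeSet(reference=HEALTHY, dl=HEALTHY, hg=HEALTHY)
        cohort = [
            _patient("none", HEALTHY, round2=None),
            _patient(
                "missing_hg",
                HEALTHY,
                round2=ModalityGradeSet(reference=HEALTHY, dl=HEALTHY, hg=None),
            ),
            _patient(
                "ref_ungradable",
                HEALTHY,
                round2=ModalityGradeSet(reference=UNGRADABLE, dl=HEALTHY, hg=HEALTHY),
            ),
            _patient(
                "hg_ungradable",
                HEALTHY,
                round2=ModalityGradeSet(reference=HEALTHY, dl=HEALTHY, hg=UNGRADABLE),
            ),
            _patient("ok", HEALTHY, round2=good),
        ]
        # missing data in either modality drops the patient from both arms;
        # modality-ungradable drops only that modality's arm
        dl_surv, dl_drop = build_followup_cohort(cohort, frozenset(), Modality.DL)
        hg_surv, hg_drop = build_followup_cohort(cohort, frozenset(), Modality.HG)
        assert dl_drop == {"none", "missing_hg", "ref_ungradable"}
        assert hg_drop == {"none", "missing_hg", "ref_ungradable", "hg_ungradable"}
        assert {r.patient_id for r in dl_surv} == {"ok", "hg_ungradable"}
        assert {r.patient_id for r in hg_surv} == {"ok"}


class TestTwoRoundStudy:
    def test_conservation_and_ground_truth_identity(self, default_config):
        """|round-2 cohort| + referred + dropout = |round-1 cohort|, and the
        round-2 reference STDR count equals surviving round-1 false negatives
        plus incident STDR among survivors."""
        records, truth = generate_cohort(replace(default_config, seed=5))
        truth = truth.set_index("patient_id")
        for arm in (Modality.DL, Modality.HG):
            res = run_two_round_study(records, arm)
            assert (
                len(res.cohort_round2)
                + len(res.round1.referred_ids)
                + len(res.round1.dropout_ids)
                == len(res.cohort_round1)
            )
            surviving_ids = {r.patient_id for r in res.cohort_round2}
            surviving_fn = len(res.round1.fn_ids & surviving_ids)
            incident = int(
                truth.loc[sorted(surviving_ids), "incident_stdr"].sum()
            )
            assert res.round2.contingency.disease_positive == surviving_fn + incident

    def test_every_patient_ends_in_exactly_one_bucket(self, default_config):
        records, _ = generate_cohort(replace(default_config, seed=7))
        res = run_two_round_study(records, Modality.DL)
        round1_ids = {r.patient_id for r in res.cohort_round1}
        survivors = {r.patient_id for r in res.cohort_round2}
        buckets = [survivors, res.round1.referred_ids, res.round1.dropout_ids]
        assert set().union(*buckets) == round1_ids
        assert sum(len(b) for b in buckets) == len(round1_ids)

    def test_higher_sensitivity_lowers_round2_prevalence(self, default_config):
        """Sweeping the HG screener's base sensitivity upward on the same
        underlying cohort weakly lowers round-2 STDR prevalence (more
        prevalent cases get referred out)."""
        prevs = []
        for base in (0.55, 0.75, 0.95):
            hg = replace(
                default_config.graders[Modality.HG],
                base_sens_dme=base,
                base_sens_sevpdr=base,
                difficulty_weight=0.0,
            )
            cfg = replace(
                default_config,
                graders={
                    Modality.DL: default_config.graders[Modality.DL],
                    Modality.HG: hg,
                },
                seed=21,
            )
            records, _ = generate_cohort(cfg)
            res = run_two_round_study(records, Modality.HG)
            ct2 = res.round2.contingency
            prevs.append(ct2.disease_positive / ct2.n)
        assert prevs[0] >= prevs[1] >= prevs[2]
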