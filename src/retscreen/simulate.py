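"""Two-round screening simulation: screen, confirm, refer, rebuild, rescreen.

The study design this module executes:

1. Every first-round patient with usable grades from all three sources is
   screened by the arm's modality (DL or HG) and adjudicated by the reference
   standard.
2. Screen positives are overread by retina specialists; only *confirmed* STDR
   (the true positives) are referred out for treatment and leave the program.
   False positives remain.
3. The second-round cohort is the first-round cohort minus the referred set
   and minus dropouts.  Dropout combines three paths:

   * no second-round data at all;
   * missing second-round data from either screening modality, which removes
     the patient from *both* arms (the program's protocol cannot follow a
     patient one modality failed to photograph);
   * a second-round assessment ungradable by the reference standard (both
     arms) or by the arm's own modality (that arm only).

4. The second screening repeats step 1 on the rebuilt cohort.

Because referral depends on the arm's own calls, the two arms diverge after
round one: each arm's round-two cohort derives only from its own decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .cohort import Modality, ModalityGradeSet, PatientRecord, validate_arm
from .grading import PatientCategory, is_stdr, patient_category
from .metrics import ContingencyTable


class SimulationError(ValueError):
    pass


@dataclass
class RoundOutcome:
    """One screening round for one arm.

    ``analyzed_ids`` are the patients entering the round's contingency table
    (cohort minus the round's exclusions); the four label sets partition it.
    ``referred_ids``/``dropout_ids`` are filled in by the study driver.
    """

    round_index: int
    arm: Modality
    cohort_ids: FrozenSet[str]
    tp_ids: FrozenSet[str]
    fp_ids: FrozenSet[str]
    tn_ids: FrozenSet[str]
    fn_ids: FrozenSet[str]
    excluded: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    referred_ids: FrozenSet[str] = frozenset()
    dropout_ids: FrozenSet[str] = frozenset()

    @property
    def analyzed_ids(self) -> FrozenSet[str]:
        return self.tp_ids | self.fp_ids | self.tn_ids | self.fn_ids

    @property
    def screen_positive_ids(self) -> FrozenSet[str]:
        return self.tp_ids | self.fp_ids

    @property
    def contingency(self) -> ContingencyTable:
        return ContingencyTable(
            tp=len(self.tp_ids),
            fp=len(self.fp_ids),
            tn=len(self.tn_ids),
            fn=len(self.fn_ids),
        )


def _category(pa) -> Optional[PatientCategory]:
    if pa is None:
        return None
    return patient_category(pa)


def screen_round(
    cohort: Sequence[PatientRecord], arm: Modality, round_index: int
) -> RoundOutcome:
    """Screen a cohort with one arm's modality against the reference standard.

    Patients lacking the round's grades, or ungradable by the reference
    standard or by the arm's modality, are excluded from the contingency
    table and recorded per cause in ``excluded``.
    """
    validate_arm(arm)
    if not cohort:
        raise SimulationError("cannot screen an empty cohort")
    tp, fp, tn, fn = set(), set(), set(), set()
    excl: Dict[str, set] = {
        "missing_grades": set(),
        "reference_ungradable": set(),
        f"{arm.value}_ungradable": set(),
    }
    for rec in cohort:
        grades = rec.grades(round_index)
        ref_pa = grades.reference if grades else None
        mod_pa = grades.get(arm) if grades else None
        if ref_pa is None or mod_pa is None:
            excl["missing_grades"].add(rec.patient_id)
            continue
        ref_cat = patient_category(ref_pa)
        mod_cat = patient_category(mod_pa)
        if ref_cat is PatientCategory.UNGRADABLE:
            excl["reference_ungradable"].add(rec.patient_id)
            continue
        if mod_cat is PatientCategory.UNGRADABLE:
            excl[f"{arm.value}_ungradable"].add(rec.patient_id)
            continue
        truth = is_stdr(ref_cat)
        call = is_stdr(mod_cat)
        (tp if truth and call else fn if truth else fp if call else tn).add(
            rec.patient_id
        )
    return RoundOutcome(
        round_index=round_index,
        arm=arm,
        cohort_ids=frozenset(r.patient_id for r in cohort),
        tp_ids=frozenset(tp),
        fp_ids=frozenset(fp),
        tn_ids=frozenset(tn),
        fn_ids=frozenset(fn),
        excluded={k: frozenset(v) for k, v in excl.items()},
    )


def confirm_and_refer(outcome: RoundOutcome) -> FrozenSet[str]:
    """Specialist overread of screen positives: exactly the true positives
    are confirmed STDR and referred out."""
    return outcome.tp_ids


def _is_dropout(rec: PatientRecord, arm: Modality) -> bool:
    g2 = rec.round2
    if g2 is None:
        return True
    if g2.dl is None or g2.hg is None:
        return True  # missing data in either modality removes from both arms
    if _category(g2.reference) in (None, PatientCategory.UNGRADABLE):
        return True
    if _category(g2.get(arm)) is PatientCategory.UNGRADABLE:
        return True
    return False


def build_followup_cohort(
    cohort: Sequence[PatientRecord],
    referred: FrozenSet[str],
    arm: Modality,
) -> Tuple[List[PatientRecord], FrozenSet[str]]:
    """Second-round cohort for one arm: remove referred patients, then
    dropouts.  Returns (survivors, dropout_ids)."""
    validate_arm(arm)
    ids = {r.patient_id for r in cohort}
    missing = referred - ids
    if missing:
        raise SimulationError(f"referred ids not in cohort: {sorted(missing)[:5]}...")
    survivors: List[PatientRecord] = []
    dropouts: set = set()
    for rec in cohort:
        if rec.patient_id in referred:
            continue
        if _is_dropout(rec, arm):
            dropouts.add(rec.patient_id)
        else:
            survivors.append(rec)
    return survivors, frozenset(dropouts)


@dataclass
class TwoRoundResult:
    """Both rounds of one arm, plus the study-entry exclusions.

    ``round2`` is ``None`` when nobody remains for a second screening
    (fully referred/dropped cohort) — callers then report round 1 only.
    """

    arm: Modality
    round1: RoundOutcome
    round2: Optional[RoundOutcome]
    study_excluded_ids: FrozenSet[str]
    cohort_round1: List[PatientRecord] = field(repr=False, default_factory=list)
    cohort_round2: List[PatientRecord] = field(repr=False, default_factory=list)


def study_cohort(records: Sequence[PatientRecord]) -> Tuple[List[PatientRecord], FrozenSet[str]]:
    """Apply the study's entry criteria: a patient is included only if all
    three sources graded the first round and none found them ungradable."""
    included: List[PatientRecord] = []
    excluded: set = set()
    for rec in records:
        g1 = rec.round1
        if g1 is None or not g1.complete:
            excluded.add(rec.patient_id)
            continue
        cats = (
            patient_category(g1.reference),
            patient_category(g1.dl),
            patient_category(g1.hg),
        )
        if PatientCategory.UNGRADABLE in cats:
            excluded.add(rec.patient_id)
        else:
            included.append(rec)
    return included, frozenset(excluded)


def run_two_round_study(
    records: Sequence[PatientRecord], arm: Modality
) -> TwoRoundResult:
    """Run the full biennial screening study for one arm.

    Enforces the conservation law |round-2 cohort| + |referred| + |dropout|
    = |round-1 cohort| on every run.
    """
    validate_arm(arm)
    cohort1, study_excluded = study_cohort(records)
    if not cohort1:
        raise SimulationError("no includable patients in the first round")
    out1 = screen_round(cohort1, arm, round_index=1)
    referred = confirm_and_refer(out1)
    cohort2, dropouts = build_followup_cohort(cohort1, referred, arm)
    out1.referred_ids = referred
    out1.dropout_ids = dropouts
    assert len(cohort2) + len(referred) + len(dropouts) == len(cohort1), (
        "cohort conservation violated between rounds"
    )
    out2 = screen_round(cohort2, arm, round_index=2) if cohort2 else None
    return TwoRoundResult(
        arm=arm,
        round1=out1,
        round2=out2,
        study_excluded_ids=study_excluded,
        cohort_round1=list(cohort1),
        cohort_round2=cohort2,
    )
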