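"""A bundled benchmark cohort reproducing the reference study's aggregates.

The nationwide biennial DR screening study this package is calibrated to
publishes its complete patient flow, contingency tables, severity margins and
progression counts, but not patient-level data.  This module constructs a
synthetic patient-level cohort of 5,738 records whose *aggregate* counts
equal every published margin exactly — individual rows are fabricated; only
the margins are constrained.  Running the two-round pipeline on it
reproduces:

* flow: 5,738 -> 669 (DL) / 519 (HG) referred -> 921 / 956 dropout ->
  4,148 / 4,263 analysed at the second screening;
* both arms' full contingency tables in both rounds
  (DL: 669/102/4932/35 then 190/84/3853/21; HG: 519/71/4963/185 then
  165/59/3915/124);
* the reference-severity margins of each analysed cohort;
* the severity-stratified 2-year progression table for all three grading
  sources (71/50/74 incident STDR of 4136/584/293 by reference, 128/57/97
  by DL detection, 73/41/57 by HG detection).

The integer allocation is direct bookkeeping from those published counts.
One structural point deserves note: a cohort in which *all* round-2 dropout
is shared between the arms cannot reproduce the tables — with a shared
dropout set the difference between the arms' surviving false negatives is
pinned to 35 by the dropout counts but to 78 by the round-2 STDR counts.
Dropout here therefore combines a shared missing-data component with
per-arm round-2 ungradability, the same hybrid rule the simulation module
implements.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .cohort import ModalityGradeSet, PatientRecord
from .grading import PatientCategory
from . import synthcohort
from .synthcohort import _FN_PA, _FP_PA, _UNGRADABLE_PA, assessment_for_category

N = PatientCategory.NO_DR
MI = PatientCategory.MILD_NO_DME
MO = PatientCategory.MODERATE_NO_DME
SE = PatientCategory.SEVERE_NO_DME
PD = PatientCategory.PDR_NO_DME
DM = PatientCategory.DME

UNGRADABLE = "ungradable"

#: published aggregate counts the benchmark cohort must reproduce
EXPECTED: Dict = {
    "round1": {"n": 5738, "stdr": 704, "dl_positive": 771, "hg_positive": 590},
    "dl": {
        "referred": 669,
        "dropout": 921,
        "n_round2": 4148,
        "round2_stdr": 211,
        "contingency_round1": (669, 102, 4932, 35),
        "contingency_round2": (190, 84, 3853, 21),
    },
    "hg": {
        "referred": 519,
        "dropout": 956,
        "n_round2": 4263,
        "round2_stdr": 289,
        "contingency_round1": (519, 71, 4963, 185),
        "contingency_round2": (165, 59, 3915, 124),
    },
    # (n_baseline, n_stdr_detected) per baseline severity and grading source
    "incidence": {
        "reference": {"no_dr": (4136, 71), "mild_no_dme": (584, 50),
                      "moderate_no_dme": (293, 74), "total": (5013, 195)},
        "dl": {"no_dr": (4136, 128), "mild_no_dme": (584, 57),
               "moderate_no_dme": (293, 97), "total": (5013, 282)},
        "hg": {"no_dr": (4136, 73), "mild_no_dme": (584, 41),
               "moderate_no_dme": (293, 57), "total": (5013, 171)},
    },
    # reference-standard severity margins of each analysed cohort
    "category_margins": {
        "round1": {N: 4152, MI: 589, MO: 293, SE: 6, PD: 47, DM: 651},
        "dl_round2": {N: 3239, MI: 448, MO: 250, SE: 7, PD: 11, DM: 193},
        "hg_round2": {N: 3256, MI: 449, MO: 269, SE: 6, PD: 17, DM: 266},
    },
}


_CallSpec = Optional[str]  # "pos" | "neg" | "ungradable" | None (missing data)


def _assessment(ref_cat: PatientCategory, call: _CallSpec):
    """One modality's assessment from its binary call and the true category:
    detections mirror the true disease, over-calls read as DME, misses read
    as moderate NPDR without DME."""
    if call is None:
        return None
    if call == UNGRADABLE:
        return _UNGRADABLE_PA
    truly_stdr = ref_cat in (SE, PD, DM)
    if call == "pos":
        return assessment_for_category(ref_cat) if truly_stdr else _FP_PA
    return _FN_PA if truly_stdr else assessment_for_category(ref_cat)


class _Builder:
    """Accumulates patient strata as (count, attribute-tuple) specs."""

    def __init__(self) -> None:
        self.specs: List[Tuple] = []

    def add(
        self,
        count: int,
        ref1: PatientCategory,
        dl1: str,
        hg1: str,
        ref2: Union[PatientCategory, str, None] = None,
        dl2: _CallSpec = "neg",
        hg2: _CallSpec = "neg",
        followup: bool = True,
    ) -> None:
        if count < 0:
            raise ValueError("negative stratum count")
        self.specs.extend([(ref1, dl1, hg1, ref2, dl2, hg2, followup)] * count)

    def build(self, seed: int) -> List[PatientRecord]:
        rng = np.random.default_rng(seed)
        n = len(self.specs)
        age = rng.normal(synthcohort.AGE_MEAN, synthcohort.AGE_SD, n).round(1)
        sex = np.where(rng.random(n) < synthcohort.FEMALE_FRAC, "F", "M")
        htn = (rng.random(n) < synthcohort.HYPERTENSION_FRAC).astype(int)
        fbs = np.clip(
            rng.normal(synthcohort.FBS_MEAN, synthcohort.FBS_SD, n), 40.0, None
        ).round(1)
        order = rng.permutation(n)  # interleave strata in the output
        records: List[PatientRecord] = []
        width = len(str(n - 1))
        for new_idx, spec_idx in enumerate(order):
            ref1, dl1, hg1, ref2, dl2, hg2, followup = self.specs[spec_idx]
            round1 = ModalityGradeSet(
                reference=assessment_for_category(ref1),
                dl=_assessment(ref1, dl1),
                hg=_assessment(ref1, hg1),
            )
            round2 = None
            if followup:
                if ref2 == UNGRADABLE:
                    ref2_pa, ref2_cat = _UNGRADABLE_PA, ref1
                else:
                    ref2_cat = ref2 if ref2 is not None else ref1
                    ref2_pa = assessment_for_category(ref2_cat)
                round2 = ModalityGradeSet(
                    reference=ref2_pa,
                    dl=_assessment(ref2_cat, dl2),
                    hg=_assessment(ref2_cat, hg2),
                )
            records.append(
                PatientRecord(
                    patient_id=f"B{new_idx:0{width}d}",
                    round1=round1,
                    round2=round2,
                    age=float(age[spec_idx]),
                    sex=str(sex[spec_idx]),
                    hypertension=int(htn[spec_idx]),
                    fbs=float(fbs[spec_idx]),
                )
            )
        return records


def build_benchmark_cohort(seed: int = 0) -> List[PatientRecord]:
    """Construct the 5,738-patient benchmark cohort.

    ``seed`` only affects cosmetic demographics and record ordering; every
    grading aggregate is fixed by construction.
    """
    b = _Builder()

    # ================= baseline STDR patients (704) =======================
    # severity mix at round 1: severe 6 / PDR 47 / DME 651
    # -- detected by both modalities: referred out of both arms (519)
    for cat, k in ((SE, 1), (PD, 35), (DM, 483)):
        b.add(k, cat, "pos", "pos", followup=False)
    # -- detected by DL only, surviving in the HG arm (115); HG rescreens
    #    them at round 2 with partial success
    for cat, (tp2, fn2) in ((SE, (2, 2)), (PD, (5, 6)), (DM, (48, 52))):
        b.add(tp2, cat, "pos", "neg", ref2=cat, hg2="pos")
        b.add(fn2, cat, "pos", "neg", ref2=cat, hg2="neg")
    # -- detected by DL only, HG-ungradable at round 2 (HG-arm dropout) (35)
    b.add(35, DM, "pos", "neg", ref2=DM, hg2=UNGRADABLE)
    # -- missed by both at round 1; persisting STDR rescreened in both arms
    #    (35: severe 1 / PDR 1 / DME 33; round-2 calls: DL 20+/15-, HG 15+/20-)
    b.add(1, SE, "neg", "neg", ref2=SE, dl2="pos", hg2="pos")
    b.add(1, PD, "neg", "neg", ref2=PD, dl2="pos", hg2="neg")
    b.add(14, DM, "neg", "neg", ref2=DM, dl2="pos", hg2="pos")
    b.add(4, DM, "neg", "neg", ref2=DM, dl2="pos", hg2="neg")
    b.add(15, DM, "neg", "neg", ref2=DM, dl2="neg", hg2="neg")

    # ================= baseline non-STDR patients (5,034) =================
    # -- reference-ungradable at round 2: dropout from both arms, no
    #    progression outcome (21)
    b.add(16, N, "neg", "neg", ref2=UNGRADABLE)
    b.add(5, MI, "neg", "neg", ref2=UNGRADABLE)

    # -- missing both modalities at round 2: shared dropout, reference
    #    outcome known (600, of which 19 incident STDR)
    for cat, k in ((N, 6), (MI, 5), (MO, 8)):
        b.add(k, cat, "neg", "neg", ref2=DM, dl2=None, hg2=None)
    for cat, k in ((N, 463), (MI, 58), (MO, 60)):
        b.add(k, cat, "neg", "neg", ref2=cat, dl2=None, hg2=None)

    # -- missing DL data at round 2: shared dropout, HG grades exist (100)
    for cat, pos, neg in ((N, 2, 78), (MI, 5, 5), (MO, 10, 0)):
        b.add(pos, cat, "neg", "neg", ref2=cat, dl2=None, hg2="pos")
        b.add(neg, cat, "neg", "neg", ref2=cat, dl2=None, hg2="neg")

    # -- missing HG data at round 2: shared dropout, DL grades exist (100)
    for cat, pos, neg in ((N, 15, 65), (MI, 5, 5), (MO, 8, 2)):
        b.add(pos, cat, "neg", "neg", ref2=cat, dl2="pos", hg2=None)
        b.add(neg, cat, "neg", "neg", ref2=cat, dl2="neg", hg2=None)

    # -- DL-ungradable at round 2: DL-arm dropout only, screened by HG (100)
    for cat, k in ((N, 63), (MI, 8), (MO, 29)):
        b.add(k, cat, "neg", "neg", ref2=cat, dl2=UNGRADABLE, hg2="neg")

    # -- HG-ungradable at round 2: HG-arm dropout only, screened by DL (100)
    #    incident STDR (37; DL detects 35)
    u2_incident = {
        N: ((SE, 2, 0), (PD, 2, 0), (DM, 10, 1)),
        MI: ((SE, 2, 0), (PD, 1, 0), (DM, 7, 0)),
        MO: ((SE, 1, 0), (PD, 2, 0), (DM, 8, 1)),
    }
    for base, rows in u2_incident.items():
        for r2cat, det, miss in rows:
            b.add(det, base, "neg", "neg", ref2=r2cat, dl2="pos", hg2=UNGRADABLE)
            b.add(miss, base, "neg", "neg", ref2=r2cat, dl2="neg", hg2=UNGRADABLE)
    #    stable non-STDR (63)
    for cat, k in ((N, 46), (MI, 7), (MO, 10)):
        b.add(k, cat, "neg", "neg", ref2=cat, dl2="neg", hg2=UNGRADABLE)

    # -- incident STDR surviving in both arms (139)
    #    per baseline: (round-2 category, dl call, hg call, count)
    surv_incident = {
        N: ((SE, "pos", "pos", 1), (PD, "pos", "pos", 1), (DM, "pos", "pos", 33),
            (DM, "pos", "neg", 13), (DM, "neg", "neg", 2)),
        MI: ((PD, "pos", "pos", 2), (DM, "pos", "pos", 23),
             (DM, "pos", "neg", 9), (DM, "neg", "neg", 1)),
        MO: ((PD, "pos", "pos", 2), (DM, "pos", "pos", 33),
             (DM, "pos", "neg", 18), (DM, "neg", "neg", 1)),
    }
    for base, rows in surv_incident.items():
        for r2cat, dl2, hg2, k in rows:
            b.add(k, base, "neg", "neg", ref2=r2cat, dl2=dl2, hg2=hg2)

    # -- stable non-STDR surviving in both arms (3,874), by progression cell
    #    no retinopathy -> no retinopathy (3,193)
    b.add(36, N, "pos", "neg", ref2=N)                   # DL round-1 FP
    b.add(58, N, "neg", "pos", ref2=N)                   # HG round-1 FP
    b.add(39, N, "neg", "neg", ref2=N, dl2="pos")        # DL round-2 FP
    b.add(36, N, "neg", "neg", ref2=N, hg2="pos")        # HG round-2 FP
    b.add(3024, N, "neg", "neg", ref2=N)
    #    no retinopathy -> mild (100)
    b.add(100, N, "neg", "neg", ref2=MI)
    #    no retinopathy -> moderate (40)
    b.add(12, N, "neg", "neg", ref2=MO, dl2="pos")
    b.add(28, N, "neg", "neg", ref2=MO)
    #    mild -> mild (341)
    b.add(11, MI, "neg", "neg", ref2=MI, hg2="pos")
    b.add(330, MI, "neg", "neg", ref2=MI)
    #    mild -> moderate (100)
    b.add(8, MI, "neg", "neg", ref2=MO, dl2="pos")
    b.add(92, MI, "neg", "neg", ref2=MO)
    #    moderate -> moderate (100); round-1 and round-2 false positives
    #    overlap here (persistently over-called patients)
    b.add(25, MO, "pos", "neg", ref2=MO, dl2="pos")
    b.add(12, MO, "pos", "neg", ref2=MO, hg2="pos")
    b.add(29, MO, "pos", "neg", ref2=MO)
    b.add(13, MO, "neg", "pos", ref2=MO)
    b.add(21, MO, "neg", "neg", ref2=MO)

    records = b.build(seed)
    assert len(records) == EXPECTED["round1"]["n"]
    return records
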