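"""Diabetic-retinopathy grading scales and eye-to-patient aggregation rules.

Grades follow the International Clinical Classification of DR (ICDR): an
ordinal severity scale (no DR < mild NPDR < moderate NPDR < severe NPDR < PDR)
plus a separate present/absent grade for diabetic macular edema (DME).

The screening endpoint is sight-threatening DR (STDR): a patient has STDR if
either eye has severe NPDR, PDR, or DME.  Patient-level severity is the
severity of the worse eye, and DME in either eye dominates the patient label
(the patient-level categories partition gradable patients into
"<severity> without DME" bins plus a single DME bin).

Ungradability: a patient is ungradable if both eyes are ungradable, or if one
eye is ungradable and the fellow eye is not STDR on its own.  (An STDR fellow
eye settles the patient label regardless of the other eye, so such patients
remain gradable.)
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class GradingError(ValueError):
    """Raised when a grading operation receives an input outside its domain."""


class DRSeverity(enum.IntEnum):
    """ICDR retinopathy severity; total order, NO_DR lowest."""

    NO_DR = 0
    MILD_NPDR = 1
    MODERATE_NPDR = 2
    SEVERE_NPDR = 3
    PDR = 4


#: CSV serialisation codes for severities (``ungradable`` handled separately).
SEVERITY_CODES = {
    DRSeverity.NO_DR: "none",
    DRSeverity.MILD_NPDR: "mild",
    DRSeverity.MODERATE_NPDR: "moderate",
    DRSeverity.SEVERE_NPDR: "severe",
    DRSeverity.PDR: "pdr",
}
SEVERITY_FROM_CODE = {v: k for k, v in SEVERITY_CODES.items()}


class PatientCategory(enum.Enum):
    """Patient-level category: worst-eye severity x DME x gradability."""

    NO_DR = "no_dr"
    MILD_NO_DME = "mild_no_dme"
    MODERATE_NO_DME = "moderate_no_dme"
    SEVERE_NO_DME = "severe_no_dme"
    PDR_NO_DME = "pdr_no_dme"
    DME = "dme"
    UNGRADABLE = "ungradable"


#: The six gradable categories, in increasing clinical concern for the
#: "no DME" run; DME is listed last (it is an STDR category regardless of
#: severity).
GRADABLE_CATEGORIES = (
    PatientCategory.NO_DR,
    PatientCategory.MILD_NO_DME,
    PatientCategory.MODERATE_NO_DME,
    PatientCategory.SEVERE_NO_DME,
    PatientCategory.PDR_NO_DME,
    PatientCategory.DME,
)

STDR_CATEGORIES = frozenset(
    {PatientCategory.SEVERE_NO_DME, PatientCategory.PDR_NO_DME, PatientCategory.DME}
)

_SEVERITY_TO_CATEGORY = {
    DRSeverity.NO_DR: PatientCategory.NO_DR,
    DRSeverity.MILD_NPDR: PatientCategory.MILD_NO_DME,
    DRSeverity.MODERATE_NPDR: PatientCategory.MODERATE_NO_DME,
    DRSeverity.SEVERE_NPDR: PatientCategory.SEVERE_NO_DME,
    DRSeverity.PDR: PatientCategory.PDR_NO_DME,
}


class StdrSubtype(enum.Enum):
    """Why a patient counts as STDR: macular edema vs advanced retinopathy."""

    DME = "dme"
    SEVERE_PDR = "severe_pdr"


@dataclass(frozen=True)
class EyeAssessment:
    """One eye's grades by one grading source.

    ``dr is None`` encodes an ungradable (or missing) photograph; grading is
    all-or-none per eye, so an ungradable eye yields neither a severity nor a
    DME grade.
    """

    dr: Optional[DRSeverity]
    dme: Optional[bool]

    def __post_init__(self) -> None:
        if (self.dr is None) != (self.dme is None):
            raise GradingError(
                "an eye is graded all-or-none: dr and dme must both be set "
                f"or both be ungradable (got dr={self.dr!r}, dme={self.dme!r})"
            )

    @classmethod
    def ungradable(cls) -> "EyeAssessment":
        return cls(dr=None, dme=None)

    @property
    def gradable(self) -> bool:
        return self.dr is not None


def eye_is_stdr(eye: EyeAssessment) -> Optional[bool]:
    """Eye-level STDR: DME present, or severity >= severe NPDR.

    Returns ``None`` (unknown) for an ungradable eye.
    """
    if not eye.gradable:
        return None
    return bool(eye.dme) or eye.dr >= DRSeverity.SEVERE_NPDR


def _category_of_gradable_pair(a: EyeAssessment, b: EyeAssessment) -> PatientCategory:
    if a.dme or b.dme:
        return PatientCategory.DME
    return _SEVERITY_TO_CATEGORY[max(a.dr, b.dr)]


def _category_of_single_eye(eye: EyeAssessment) -> PatientCategory:
    if eye.dme:
        return PatientCategory.DME
    return _SEVERITY_TO_CATEGORY[eye.dr]


@dataclass(frozen=True)
class PatientAssessment:
    """Both eyes of one patient as graded by one source.

    A missing photograph is encoded as a fully ungradable eye.
    """

    right_eye: EyeAssessment
    left_eye: EyeAssessment

    def category(self) -> PatientCategory:
        return patient_category(self)

    def is_stdr(self) -> bool:
        return is_stdr(self.category())


def patient_category(pa: PatientAssessment) -> PatientCategory:
    """Patient-level category from the two eye assessments.

    Rules, in order:

    * both eyes ungradable -> UNGRADABLE;
    * exactly one eye ungradable -> the patient is gradable only if the fellow
      eye is STDR on its own (its category then stands for the patient),
      otherwise UNGRADABLE;
    * both eyes gradable -> DME if either eye has DME, else the worse eye's
      severity mapped to the "no DME" categories.
    """
    r, l = pa.right_eye, pa.left_eye
    if not r.gradable and not l.gradable:
        return PatientCategory.UNGRADABLE
    if r.gradable and l.gradable:
        return _category_of_gradable_pair(r, l)
    fellow = r if r.gradable else l
    if eye_is_stdr(fellow):
        return _category_of_single_eye(fellow)
    return PatientCategory.UNGRADABLE


def is_stdr(cat: PatientCategory) -> bool:
    """Whether a patient-level category is sight-threatening DR.

    Raises ``GradingError`` for UNGRADABLE: such patients must be excluded
    from analysis, not classified.
    """
    if cat is PatientCategory.UNGRADABLE:
        raise GradingError("an ungradable patient cannot be classified as STDR or not")
    return cat in STDR_CATEGORIES


def stdr_subtype(cat: PatientCategory) -> StdrSubtype:
    """Split an STDR category into DME vs severe-NPDR/PDR."""
    if cat is PatientCategory.DME:
        return StdrSubtype.DME
    if cat in (PatientCategory.SEVERE_NO_DME, PatientCategory.PDR_NO_DME):
        return StdrSubtype.SEVERE_PDR
    raise GradingError(f"{cat} is not an STDR category")
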