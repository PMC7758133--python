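"""Patient-level records for a two-round screening cohort.

Every patient is graded by three sources ("modalities"): the reference
standard (adjudicated retina specialists, treated as truth), a deep-learning
system (DL), and trained human graders (HG).  DL and HG are the two screening
arms; the reference standard is never an arm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .grading import PatientAssessment


class Modality(enum.Enum):
    REFERENCE = "reference"
    DL = "dl"
    HG = "hg"


#: The two screening arms (the reference standard only adjudicates).
ARMS = (Modality.DL, Modality.HG)


def validate_arm(arm: Modality) -> Modality:
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {[a.value for a in ARMS]}, got {arm!r}")
    return arm


@dataclass(frozen=True)
class ModalityGradeSet:
    """One round's patient assessments by the three grading sources.

    At the first screening an includable patient has all three present.
    At the second screening an assessment may be ``None``, meaning that
    source produced no data for the round (missing photographs / records).
    """

    reference: Optional[PatientAssessment]
    dl: Optional[PatientAssessment]
    hg: Optional[PatientAssessment]

    def get(self, modality: Modality) -> Optional[PatientAssessment]:
        return {
            Modality.REFERENCE: self.reference,
            Modality.DL: self.dl,
            Modality.HG: self.hg,
        }[modality]

    @property
    def complete(self) -> bool:
        return (
            self.reference is not None and self.dl is not None and self.hg is not None
        )


@dataclass
class PatientRecord:
    """One patient across the two screening rounds.

    ``round2 is None`` means the patient has no second-round data at all
    (e.g. referred out of the program after the first screening).
    ``latent_difficulty`` exists only in synthetic cohorts (the generator's
    hidden case-difficulty variable); analysis stages never read it.
    """

    patient_id: str
    round1: ModalityGradeSet
    round2: Optional[ModalityGradeSet] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    hypertension: Optional[int] = None
    fbs: Optional[float] = None
    latent_difficulty: Optional[float] = field(default=None, repr=False, compare=False)

    def grades(self, round_index: int) -> Optional[ModalityGradeSet]:
        if round_index == 1:
            return self.round1
        if round_index == 2:
            return self.round2
        raise ValueError(f"round_index must be 1 or 2, got {round_index}")
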