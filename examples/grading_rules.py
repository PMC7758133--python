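"""Patient-level grading: worse-eye severity, DME dominance, ungradability.

Builds a handful of two-eye assessments and prints the patient category and
sight-threatening-DR (STDR) label each one receives.
"""

from retscreen import (
    DRSeverity,
    EyeAssessment,
    PatientAssessment,
    PatientCategory,
    is_stdr,
    patient_category,
)

UG = EyeAssessment.ungradable()

cases = [
    ("worse-eye rule", EyeAssessment(DRSeverity.MODERATE_NPDR, False),
     EyeAssessment(DRSeverity.MILD_NPDR, False)),
    ("DME dominates severity", EyeAssessment(DRSeverity.PDR, False),
     EyeAssessment(DRSeverity.MILD_NPDR, True)),
    ("one eye ungradable, fellow not STDR", UG,
     EyeAssessment(DRSeverity.MODERATE_NPDR, False)),
    ("one eye ungradable, fellow STDR", UG,
     EyeAssessment(DRSeverity.NO_DR, True)),
    ("both eyes ungradable", UG, UG),
]

for label, right, left in cases:
    cat = patient_category(PatientAssessment(right, left))
    stdr = "excluded" if cat is PatientCategory.UNGRADABLE else (
        "STDR" if is_stdr(cat) else "not STDR"
    )
    print(f"{label:38s} -> {cat.value:16s} ({stdr})")

# A patient is STDR when either eye has severe NPDR, PDR or DME; a patient
# with one ungradable eye stays in the analysis only if the fellow eye is
# STDR on its own (its grade then decides the label).
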