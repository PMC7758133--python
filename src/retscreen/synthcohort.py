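"""Synthetic longitudinal screening cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes: a baseline case mix over the six gradable patient categories, a
2-year discrete progression step (row-stochastic transition matrix, no
regression to milder disease for non-referred patients), and imperfect
screeners whose errors depend on a latent per-patient case difficulty.

Mechanism of the case-spectrum shift
------------------------------------
Each patient carries ``latent_difficulty`` u ~ Uniform(0, 1), shared by both
screening modalities (difficulty is a property of the case, not the grader)
and constant across rounds.  A modality detects a true STDR patient with
probability ``base_sens(subtype) - difficulty_weight * d`` (clipped to
[0, 1]), so a first screening preferentially removes easy cases and leaves
hard false negatives behind.  STDR that is *incident* at the second round is
new-onset, subtler disease: its effective difficulty is shifted upward,
``d = min(1, u + incident_difficulty_boost)``.  Together these reproduce the
falling prevalence and falling sensitivity observed at a second screening.
With ``difficulty_weight = 0`` errors are independent of the case and the
sensitivity drop vanishes.

False positives arise from non-STDR patients with probability
``(1 - base_spec)``, multiplied by ``fp_moderate_boost`` for moderate-NPDR
patients (the category screeners most often over-call).

Reproducibility: a cohort is a pure function of (config, seed).  Every random
variable is drawn from its own named child stream of the seed, with patient
``i`` consuming element ``i``; enlarging the cohort therefore never
reshuffles earlier patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import ARMS, Modality, ModalityGradeSet, PatientRecord
from .grading import (
    DRSeverity,
    EyeAssessment,
    GRADABLE_CATEGORIES,
    PatientAssessment,
    PatientCategory,
    StdrSubtype,
    stdr_subtype,
)
from .simulate import run_two_round_study

_N_CAT = len(GRADABLE_CATEGORIES)
_CAT_INDEX = {c: i for i, c in enumerate(GRADABLE_CATEGORIES)}
_STDR_MASK = np.array([i >= 3 for i in range(_N_CAT)])  # severe, pdr, dme
_DME_IDX = _CAT_INDEX[PatientCategory.DME]
_MODERATE_IDX = _CAT_INDEX[PatientCategory.MODERATE_NO_DME]


@dataclass(frozen=True)
class GraderParams:
    """Error model for one screening modality."""

    base_sens_dme: float
    base_sens_sevpdr: float
    base_spec: float
    fp_moderate_boost: float
    difficulty_weight: float

    def __post_init__(self) -> None:
        for name in ("base_sens_dme", "base_sens_sevpdr", "base_spec"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fp_moderate_boost < 0 or self.difficulty_weight < 0:
            raise ValueError("fp_moderate_boost and difficulty_weight must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters; (config, seed) fully determines the cohort."""

    n_patients: int
    baseline_probs: Tuple[float, ...]  # over the six gradable categories
    transition: Tuple[Tuple[float, ...], ...]  # 6x6 row-stochastic, 2-year step
    graders: Dict[Modality, GraderParams]
    eye_concordance: float = 0.25
    ungradable_rate: float = 0.005
    dropout_rate: float = 0.17
    incident_difficulty_boost: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        bp = np.asarray(self.baseline_probs, dtype=float)
        tr = np.asarray(self.transition, dtype=float)
        if bp.shape != (_N_CAT,):
            raise ValueError(f"baseline_probs must have length {_N_CAT}")
        if tr.shape != (_N_CAT, _N_CAT):
            raise ValueError(f"transition must be {_N_CAT}x{_N_CAT}")
        if (bp < 0).any() or (tr < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(bp.sum() - 1.0) > 1e-12:
            raise ValueError("baseline_probs must sum to 1 within 1e-12")
        rowsum = tr.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > 1e-12:
            raise ValueError("each transition row must sum to 1 within 1e-12")
        for rate in (self.eye_concordance, self.ungradable_rate, self.dropout_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.incident_difficulty_boost < 0:
            raise ValueError("incident_difficulty_boost must be >= 0")
        if set(self.graders) != set(ARMS):
            raise ValueError("graders must be specified for exactly DL and HG")

    @property
    def baseline(self) -> np.ndarray:
        return np.asarray(self.baseline_probs, dtype=float)

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.asarray(self.transition, dtype=float)


# --- demographic moments the generator matches (cosmetic covariates) -------
AGE_MEAN, AGE_SD = 57.27, 10.44
FEMALE_FRAC = 0.688
HYPERTENSION_FRAC = 0.679
FBS_MEAN, FBS_SD = 151.26, 52.83


_STREAM_NAMES = (
    "baseline",
    "difficulty",
    "transition",
    "eye_r1",
    "eye_r2",
    "det_dl_r1",
    "det_dl_r2",
    "det_hg_r1",
    "det_hg_r2",
    "ungr_reference_r1",
    "ungr_dl_r1",
    "ungr_hg_r1",
    "ungr_reference_r2",
    "ungr_dl_r2",
    "ungr_hg_r2",
    "dropout",
    "age",
    "sex",
    "htn",
    "fbs",
)


def _streams(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAM_NAMES, children)}


# Shared immutable eye-assessment building blocks (cheap record construction).
_UNGRADABLE_EYE = EyeAssessment.ungradable()
_UNGRADABLE_PA = PatientAssessment(_UNGRADABLE_EYE, _UNGRADABLE_EYE)
_HEALTHY_EYE = EyeAssessment(DRSeverity.NO_DR, False)

_WORSE_EYE = {
    PatientCategory.NO_DR: _HEALTHY_EYE,
    PatientCategory.MILD_NO_DME: EyeAssessment(DRSeverity.MILD_NPDR, False),
    PatientCategory.MODERATE_NO_DME: EyeAssessment(DRSeverity.MODERATE_NPDR, False),
    PatientCategory.SEVERE_NO_DME: EyeAssessment(DRSeverity.SEVERE_NPDR, False),
    PatientCategory.PDR_NO_DME: EyeAssessment(DRSeverity.PDR, False),
    PatientCategory.DME: EyeAssessment(DRSeverity.MODERATE_NPDR, True),
}

#: assessments keyed by (category, fellow_shares_stdr)
_ASSESSMENT: Dict[Tuple[PatientCategory, bool], PatientAssessment] = {}
for _cat, _worse in _WORSE_EYE.items():
    _ASSESSMENT[(_cat, False)] = PatientAssessment(_worse, _HEALTHY_EYE)
    _ASSESSMENT[(_cat, True)] = PatientAssessment(_worse, _worse)

_FN_PA = _ASSESSMENT[(PatientCategory.MODERATE_NO_DME, False)]  # a miss reads as moderate
_FP_PA = _ASSESSMENT[(PatientCategory.DME, False)]  # an over-call reads as DME


def assessment_for_category(
    cat: PatientCategory, fellow_shares_stdr: bool = False
) -> PatientAssessment:
    """A canonical two-eye assessment realising a patient category.

    The worse (right) eye carries the category; the fellow eye is healthy
    unless ``fellow_shares_stdr`` and the category is STDR, in which case it
    mirrors the worse eye (bilateral disease).
    """
    if cat is PatientCategory.UNGRADABLE:
        return _UNGRADABLE_PA
    key_bilateral = fellow_shares_stdr and _CAT_INDEX[cat] >= 3
    return _ASSESSMENT[(cat, key_bilateral)]


def _detection_probs(
    gp: GraderParams, cat_idx: np.ndarray, difficulty: np.ndarray
) -> np.ndarray:
    """Per-patient probability of an STDR-positive call (vectorised)."""
    base_sens = np.where(
        cat_idx == _DME_IDX, gp.base_sens_dme, gp.base_sens_sevpdr
    )
    p_detect = np.clip(base_sens - gp.difficulty_weight * difficulty, 0.0, 1.0)
    p_fp = np.clip(
        (1.0 - gp.base_spec)
        * np.where(cat_idx == _MODERATE_IDX, gp.fp_moderate_boost, 1.0),
        0.0,
        1.0,
    )
    return np.where(_STDR_MASK[cat_idx], p_detect, p_fp)


def generate_cohort(
    config: SyntheticConfig,
) -> Tuple[List[PatientRecord], pd.DataFrame]:
    """Draw a cohort and its ground-truth log.

    The log carries, per patient, the true category at each round, the latent
    difficulty, every modality's call and ungradability draw, and the dropout
    flag — enough to recompute any downstream metric in expectation.
    """
    n = config.n_patients
    rng = _streams(config.seed)

    base_cum = np.cumsum(config.baseline)
    cat1 = np.searchsorted(base_cum, rng["baseline"].random(n), side="right")
    cat1 = np.minimum(cat1, _N_CAT - 1)

    difficulty = rng["difficulty"].random(n)

    trans_cum = np.cumsum(config.transition_matrix, axis=1)
    u_trans = rng["transition"].random(n)
    cat2 = (u_trans[:, None] > trans_cum[cat1]).sum(axis=1)
    cat2 = np.minimum(cat2, _N_CAT - 1)

    stdr1 = _STDR_MASK[cat1]
    stdr2 = _STDR_MASK[cat2]
    incident = ~stdr1 & stdr2
    difficulty2 = np.where(
        incident,
        np.minimum(1.0, difficulty + config.incident_difficulty_boost),
        difficulty,
    )

    calls: Dict[Tuple[Modality, int], np.ndarray] = {}
    for arm in ARMS:
        gp = config.graders[arm]
        calls[(arm, 1)] = rng[f"det_{arm.value}_r1"].random(n) < _detection_probs(
            gp, cat1, difficulty
        )
        calls[(arm, 2)] = rng[f"det_{arm.value}_r2"].random(n) < _detection_probs(
            gp, cat2, difficulty2
        )

    ungr = {
        (mod, r): rng[f"ungr_{mod.value}_r{r}"].random(n) < config.ungradable_rate
        for mod in Modality
        for r in (1, 2)
    }
    dropout = rng["dropout"].random(n) < config.dropout_rate
    bilateral1 = rng["eye_r1"].random(n) < config.eye_concordance
    bilateral2 = rng["eye_r2"].random(n) < config.eye_concordance

    age = rng["age"].normal(AGE_MEAN, AGE_SD, n).round(1)
    sex = np.where(rng["sex"].random(n) < FEMALE_FRAC, "F", "M")
    htn = (rng["htn"].random(n) < HYPERTENSION_FRAC).astype(int)
    fbs = np.clip(rng["fbs"].normal(FBS_MEAN, FBS_SD, n), 40.0, None).round(1)

    cats = GRADABLE_CATEGORIES

    def _modality_pa(
        true_cat: PatientCategory, positive: bool, ungradable: bool, bilateral: bool
    ) -> PatientAssessment:
        if ungradable:
            return _UNGRADABLE_PA
        truly_stdr = _CAT_INDEX[true_cat] >= 3
        if positive:
            return (
                assessment_for_category(true_cat, bilateral) if truly_stdr else _FP_PA
            )
        return _FN_PA if truly_stdr else assessment_for_category(true_cat, False)

    records: List[PatientRecord] = []
    width = len(str(n - 1))
    for i in range(n):
        c1, c2 = cats[cat1[i]], cats[cat2[i]]
        ref1 = (
            _UNGRADABLE_PA
            if ungr[(Modality.REFERENCE, 1)][i]
            else assessment_for_category(c1, bilateral1[i])
        )
        ref2 = (
            _UNGRADABLE_PA
            if ungr[(Modality.REFERENCE, 2)][i]
            else assessment_for_category(c2, bilateral2[i])
        )
        round1 = ModalityGradeSet(
            reference=ref1,
            dl=_modality_pa(
                c1, calls[(Modality.DL, 1)][i], ungr[(Modality.DL, 1)][i], bilateral1[i]
            ),
            hg=_modality_pa(
                c1, calls[(Modality.HG, 1)][i], ungr[(Modality.HG, 1)][i], bilateral1[i]
            ),
        )
        if dropout[i]:
            round2 = ModalityGradeSet(reference=ref2, dl=None, hg=None)
        else:
            round2 = ModalityGradeSet(
                reference=ref2,
                dl=_modality_pa(
                    c2,
                    calls[(Modality.DL, 2)][i],
                    ungr[(Modality.DL, 2)][i],
                    bilateral2[i],
                ),
                hg=_modality_pa(
                    c2,
                    calls[(Modality.HG, 2)][i],
                    ungr[(Modality.HG, 2)][i],
                    bilateral2[i],
                ),
            )
        records.append(
            PatientRecord(
                patient_id=f"S{i:0{width}d}",
                round1=round1,
                round2=round2,
                age=float(age[i]),
                sex=str(sex[i]),
                hypertension=int(htn[i]),
                fbs=float(fbs[i]),
                latent_difficulty=float(difficulty[i]),
            )
        )

    log = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "true_cat_r1": [cats[j].value for j in cat1],
            "true_cat_r2": [cats[j].value for j in cat2],
            "incident_stdr": incident,
            "latent_difficulty": difficulty,
            "difficulty_r2": difficulty2,
            "dl_call_r1": calls[(Modality.DL, 1)],
            "dl_call_r2": calls[(Modality.DL, 2)],
            "hg_call_r1": calls[(Modality.HG, 1)],
            "hg_call_r2": calls[(Modality.HG, 2)],
            "ref_ungradable_r1": ungr[(Modality.REFERENCE, 1)],
            "ref_ungradable_r2": ungr[(Modality.REFERENCE, 2)],
            "dl_ungradable_r1": ungr[(Modality.DL, 1)],
            "dl_ungradable_r2": ungr[(Modality.DL, 2)],
            "hg_ungradable_r1": ungr[(Modality.HG, 1)],
            "hg_ungradable_r2": ungr[(Modality.HG, 2)],
            "dropout": dropout,
        }
    )
    return records, log


# ---------------------------------------------------------------------------
# calibrated defaults


def _default_transition() -> Tuple[Tuple[float, ...], ...]:
    """2-year progression rows calibrated to observed severity-stratified
    STDR incidence (1.72% / 8.56% / 25.26% for none / mild / moderate), with
    91% of incident STDR due to DME and no regression to milder disease."""

    def stdr_split(mass: float) -> Tuple[float, float, float]:
        return (0.03 * mass, 0.06 * mass, 0.91 * mass)  # severe, pdr, dme

    rows = np.zeros((_N_CAT, _N_CAT))
    # from NO_DR: STDR mass 0.0172
    se, pd_, dm = stdr_split(0.0172)
    rows[0] = (0.9000, 0.0600, 0.0228, se, pd_, dm)
    # from MILD: STDR mass 0.0856
    se, pd_, dm = stdr_split(0.0856)
    rows[1] = (0.0, 0.8200, 0.0944, se, pd_, dm)
    # from MODERATE: STDR mass 0.2526
    se, pd_, dm = stdr_split(0.2526)
    rows[2] = (0.0, 0.0, 0.7474, se, pd_, dm)
    # STDR states persist (non-referred patients are untreated)
    rows[3] = (0.0, 0.0, 0.0, 0.6, 0.4, 0.0)
    rows[4] = (0.0, 0.0, 0.0, 0.0, 1.0, 0.0)
    rows[5] = (0.0, 0.0, 0.0, 0.0, 0.0, 1.0)
    rows /= rows.sum(axis=1, keepdims=True)  # absorb rounding to 1e-16
    return tuple(tuple(float(v) for v in row) for row in rows)


def paper_default_config(n_patients: int = 5738, seed: int = 0) -> SyntheticConfig:
    """Defaults calibrated to the reference biennial screening study.

    Expected values under this config: round-1 STDR prevalence 12.27%,
    DL-like mean sensitivity 0.95 and specificity ~0.98, HG-like mean
    sensitivity 0.74 and specificity ~0.986, ~91-92% of STDR due to DME,
    and per-arm round-2 attrition ~18%.
    """
    baseline = (4152, 589, 293, 6, 47, 651)
    total = sum(baseline)
    return SyntheticConfig(
        n_patients=n_patients,
        baseline_probs=tuple(b / total for b in baseline),
        transition=_default_transition(),
        graders={
            Modality.DL: GraderParams(
                base_sens_dme=1.0,
                base_sens_sevpdr=1.0,
                base_spec=0.992,
                fp_moderate_boost=27.5,
                difficulty_weight=0.10,
            ),
            Modality.HG: GraderParams(
                base_sens_dme=0.98,
                base_sens_sevpdr=0.98,
                base_spec=0.988,
                fp_moderate_boost=4.0,
                difficulty_weight=0.48,
            ),
        },
        eye_concordance=0.25,
        ungradable_rate=0.005,
        dropout_rate=0.17,
        incident_difficulty_boost=0.35,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# analytic expectations (oracles for calibration and parameter recovery)


def expected_round1_prevalence(config: SyntheticConfig) -> float:
    return float(config.baseline[_STDR_MASK].sum())


def expected_round1_sensitivity(config: SyntheticConfig, arm: Modality) -> float:
    """Mean detection probability over the baseline STDR mix and the
    Uniform(0,1) difficulty distribution (no clipping in the valid range)."""
    gp = config.graders[arm]
    probs = config.baseline[_STDR_MASK]
    probs = probs / probs.sum()
    sens = []
    for idx, w in zip(np.flatnonzero(_STDR_MASK), probs):
        base = gp.base_sens_dme if idx == _DME_IDX else gp.base_sens_sevpdr
        sens.append(w * (base - gp.difficulty_weight / 2))
    return float(sum(sens))


def expected_round1_specificity(config: SyntheticConfig, arm: Modality) -> float:
    gp = config.graders[arm]
    probs = config.baseline[~_STDR_MASK]
    probs = probs / probs.sum()
    fp = []
    for idx, w in zip(np.flatnonzero(~_STDR_MASK), probs):
        rate = (1 - gp.base_spec) * (
            gp.fp_moderate_boost if idx == _MODERATE_IDX else 1.0
        )
        fp.append(w * min(rate, 1.0))
    return float(1 - sum(fp))


def expected_stdr_mass(config: SyntheticConfig, baseline_cat: PatientCategory) -> float:
    """Analytic 2-year STDR incidence from one non-STDR baseline category:
    the transition-row mass landing in the three STDR states."""
    row = config.transition_matrix[_CAT_INDEX[baseline_cat]]
    return float(row[_STDR_MASK].sum())


def expected_dropout_fraction(config: SyntheticConfig) -> float:
    """Expected per-arm round-2 attrition among non-referred patients:
    missing data, reference-ungradable, or arm-ungradable at round 2."""
    keep = (1 - config.dropout_rate) * (1 - config.ungradable_rate) ** 2
    return float(1 - keep)


# ---------------------------------------------------------------------------
# the spectrum-shift experiment


@dataclass(frozen=True)
class ArmShiftSummary:
    """Monte-Carlo means and standard errors for one arm across replicates."""

    arm: str
    n_reps: int
    sens_r1: float
    sens_r1_se: float
    sens_r2: float
    sens_r2_se: float
    sens_drop: float  # round1 - round2, positive = degradation
    sens_drop_se: float
    prev_r1: float
    prev_r1_se: float
    prev_r2: float
    prev_r2_se: float


def _mc(values: Sequence[float]) -> Tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(len(arr)))


def spectrum_shift_experiment(
    config: SyntheticConfig,
    n_reps: int = 50,
    seed: int = 0,
    arms: Sequence[Modality] = ARMS,
) -> Dict[str, ArmShiftSummary]:
    """Replicate the two-round study on fresh cohorts and summarise the
    round-1 -> round-2 change in sensitivity and prevalence per arm."""
    if n_reps < 2:
        raise ValueError("need at least 2 replicates for Monte-Carlo errors")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    acc: Dict[Modality, Dict[str, List[float]]] = {
        arm: {k: [] for k in ("s1", "s2", "p1", "p2")} for arm in arms
    }
    for rep_seed in child_seeds:
        cfg = replace(config, seed=int(rep_seed))
        records, _ = generate_cohort(cfg)
        for arm in arms:
            res = run_two_round_study(records, arm)
            ct1, ct2 = res.round1.contingency, res.round2.contingency
            acc[arm]["s1"].append(ct1.tp / ct1.disease_positive)
            acc[arm]["s2"].append(ct2.tp / ct2.disease_positive)
            acc[arm]["p1"].append(ct1.disease_positive / ct1.n)
            acc[arm]["p2"].append(ct2.disease_positive / ct2.n)
    out: Dict[str, ArmShiftSummary] = {}
    for arm in arms:
        s1, s1se = _mc(acc[arm]["s1"])
        s2, s2se = _mc(acc[arm]["s2"])
        drops = np.subtract(acc[arm]["s1"], acc[arm]["s2"])
        d, dse = _mc(drops)
        p1, p1se = _mc(acc[arm]["p1"])
        p2, p2se = _mc(acc[arm]["p2"])
        out[arm.value] = ArmShiftSummary(
            arm=arm.value,
            n_reps=n_reps,
            sens_r1=s1,
            sens_r1_se=s1se,
            sens_r2=s2,
            sens_r2_se=s2se,
            sens_drop=d,
            sens_drop_se=dse,
            prev_r1=p1,
            prev_r1_se=p1se,
            prev_r2=p2,
            prev_r2_se=p2se,
        )
    return out
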