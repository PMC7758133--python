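"""Screening-performance statistics.

Contingency-table metrics (sensitivity, specificity, PPV, NPV, accuracy) are
reported as percentages with Wald (normal-approximation) 95% confidence
intervals; between-round comparisons use Pearson's chi-squared test without
continuity correction, treating the two rounds as independent samples.  Both
choices reproduce the conventions of the screening-program reports this
package analyses; the independence assumption is a deliberate fidelity choice
even though the round-two cohort is a subset of round one (see the methods
note for the caveat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Modality, PatientRecord, validate_arm
from .grading import (
    GradingError,
    PatientCategory,
    StdrSubtype,
    eye_is_stdr,
    is_stdr,
    patient_category,
    stdr_subtype,
)


class UndefinedMetricError(ZeroDivisionError):
    """A metric whose denominator is empty is undefined, not zero."""


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/TN/FN counts for STDR detection in one round by one modality."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def disease_positive(self) -> int:
        return self.tp + self.fn

    @property
    def screen_positive(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricResult:
    """A proportion in percent with its CI and the counts behind it."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")


def wald_ci(successes: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Wald binomial interval, in percent, clipped to [0, 100].

    p-hat +/- z * sqrt(p-hat (1 - p-hat) / n) with z the standard-normal
    quantile for the requested two-sided level.
    """
    if n <= 0:
        raise UndefinedMetricError("Wald interval needs n > 0")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, n], got {successes}/{n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p = successes / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return 100 * max(p - half, 0.0), 100 * min(p + half, 1.0)


def proportion(numerator: int, denominator: int, level: float = 0.95) -> MetricResult:
    """A percentage with its Wald CI; the primitive behind every metric."""
    if denominator <= 0:
        raise UndefinedMetricError("proportion with empty denominator is undefined")
    low, high = wald_ci(numerator, denominator, level)
    return MetricResult(
        estimate=100 * numerator / denominator,
        ci_low=low,
        ci_high=high,
        numerator=numerator,
        denominator=denominator,
    )


def sensitivity(ct: ContingencyTable, level: float = 0.95) -> MetricResult:
    return proportion(ct.tp, ct.tp + ct.fn, level)


def specificity(ct: ContingencyTable, level: float = 0.95) -> MetricResult:
    return proportion(ct.tn, ct.tn + ct.fp, level)


def ppv(ct: ContingencyTable, level: float = 0.95) -> MetricResult:
    return proportion(ct.tp, ct.tp + ct.fp, level)


def npv(ct: ContingencyTable, level: float = 0.95) -> MetricResult:
    return proportion(ct.tn, ct.tn + ct.fn, level)


def accuracy(ct: ContingencyTable, level: float = 0.95) -> MetricResult:
    return proportion(ct.tp + ct.tn, ct.n, level)


#: metric name -> (numerator, denominator) extractors on a ContingencyTable
_METRIC_COUNTS = {
    "sensitivity": lambda ct: (ct.tp, ct.tp + ct.fn),
    "specificity": lambda ct: (ct.tn, ct.tn + ct.fp),
    "ppv": lambda ct: (ct.tp, ct.tp + ct.fp),
    "npv": lambda ct: (ct.tn, ct.tn + ct.fn),
    "accuracy": lambda ct: (ct.tp + ct.tn, ct.n),
    "prevalence": lambda ct: (ct.tp + ct.fn, ct.n),
    "screen_positive_rate": lambda ct: (ct.tp + ct.fp, ct.n),
}

METRIC_NAMES = tuple(_METRIC_COUNTS)


def metric_from_table(name: str, ct: ContingencyTable, level: float = 0.95) -> MetricResult:
    try:
        num, den = _METRIC_COUNTS[name](ct)
    except KeyError:
        raise KeyError(f"unknown metric {name!r}; choose from {METRIC_NAMES}") from None
    return proportion(num, den, level)


def chi2_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on [[a, b], [c, d]]."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-squared is undefined when a margin is zero")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


@dataclass(frozen=True)
class RoundComparison:
    """One metric compared between the first and second screening.

    ``difference`` is round2 - round1 in percentage points (decreases print
    as negative); the chi-squared contrasts numerator vs complement across
    rounds, treating them as independent samples.
    """

    metric: str
    round1: MetricResult
    round2: MetricResult
    difference: float
    chi2: float
    p: float


def compare_rounds(
    metric: str, ct1: ContingencyTable, ct2: ContingencyTable, level: float = 0.95
) -> RoundComparison:
    m1 = metric_from_table(metric, ct1, level)
    m2 = metric_from_table(metric, ct2, level)
    stat, p = chi2_2x2(
        m1.numerator,
        m1.denominator - m1.numerator,
        m2.numerator,
        m2.denominator - m2.numerator,
    )
    return RoundComparison(
        metric=metric,
        round1=m1,
        round2=m2,
        difference=m2.estimate - m1.estimate,
        chi2=stat,
        p=p,
    )


# ---------------------------------------------------------------------------
# cohort-level summaries


def _ref_category(record: PatientRecord, round_index: int) -> Optional[PatientCategory]:
    grades = record.grades(round_index)
    if grades is None or grades.reference is None:
        return None
    return patient_category(grades.reference)


def prevalence(
    cohort: Sequence[PatientRecord],
    round_index: int = 1,
    modality: Modality = Modality.REFERENCE,
    level: float = 0.95,
) -> MetricResult:
    """STDR prevalence among patients gradable by ``modality`` in the round."""
    if not cohort:
        raise UndefinedMetricError("prevalence of an empty cohort is undefined")
    num = den = 0
    for rec in cohort:
        grades = rec.grades(round_index)
        if grades is None:
            continue
        pa = grades.get(modality)
        if pa is None:
            continue
        cat = patient_category(pa)
        if cat is PatientCategory.UNGRADABLE:
            continue
        den += 1
        num += is_stdr(cat)
    return proportion(num, den, level)


#: non-STDR baseline severities reported in progression tables, in order.
BASELINE_LEVELS = (
    PatientCategory.NO_DR,
    PatientCategory.MILD_NO_DME,
    PatientCategory.MODERATE_NO_DME,
)


def incidence_by_baseline(
    cohort: Sequence[PatientRecord],
    detection_source: Modality = Modality.REFERENCE,
) -> pd.DataFrame:
    """2-year STDR progression stratified by baseline reference severity.

    Denominators: patients non-STDR at the first screening per the reference
    standard, gradable by the reference standard at the second screening,
    binned by their baseline reference category.  The outcome column counts
    patients whose *second-round* grade by ``detection_source`` is STDR
    (for DL/HG this is the modality's detection call; patients without a
    usable grade from that source count as not detected).  Returns one row
    per baseline level plus a ``total`` row.
    """
    if not isinstance(detection_source, Modality):
        raise ValueError(f"unknown grading source {detection_source!r}")
    n_baseline: Dict[PatientCategory, int] = {c: 0 for c in BASELINE_LEVELS}
    n_stdr: Dict[PatientCategory, int] = {c: 0 for c in BASELINE_LEVELS}
    for rec in cohort:
        base = _ref_category(rec, 1)
        if base is None or base is PatientCategory.UNGRADABLE or is_stdr(base):
            continue
        ref2 = _ref_category(rec, 2)
        if ref2 is None or ref2 is PatientCategory.UNGRADABLE:
            continue  # no second-round reference outcome
        n_baseline[base] += 1
        pa = rec.round2.get(detection_source)
        if pa is None:
            continue
        cat = patient_category(pa)
        if cat is not PatientCategory.UNGRADABLE and is_stdr(cat):
            n_stdr[base] += 1
    rows = []
    for cat in BASELINE_LEVELS:
        den, num = n_baseline[cat], n_stdr[cat]
        rows.append(
            {
                "baseline": cat.value,
                "n_baseline": den,
                "n_stdr": num,
                "pct_stdr": 100 * num / den if den else float("nan"),
            }
        )
    tot_den = sum(n_baseline.values())
    tot_num = sum(n_stdr.values())
    rows.append(
        {
            "baseline": "total",
            "n_baseline": tot_den,
            "n_stdr": tot_num,
            "pct_stdr": 100 * tot_num / tot_den if tot_den else float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("baseline")


def stdr_breakdown(categories: Iterable[PatientCategory]) -> Dict[StdrSubtype, float]:
    """Fractions (in percent) of DME vs severe-NPDR/PDR in a set of STDR cases."""
    counts = {StdrSubtype.DME: 0, StdrSubtype.SEVERE_PDR: 0}
    total = 0
    for cat in categories:
        counts[stdr_subtype(cat)] += 1  # raises on non-STDR input
        total += 1
    if total == 0:
        raise UndefinedMetricError("breakdown of an empty case set is undefined")
    return {sub: 100 * c / total for sub, c in counts.items()}


def moderate_no_dme_fraction(categories: Iterable[PatientCategory]) -> float:
    """Percent of a non-STDR case set (e.g. false positives) that is
    moderate NPDR without DME."""
    cats = list(categories)
    if not cats:
        raise UndefinedMetricError("breakdown of an empty case set is undefined")
    for cat in cats:
        if cat is PatientCategory.UNGRADABLE or is_stdr(cat):
            raise GradingError(f"{cat} is not a gradable non-STDR category")
    mod = sum(c is PatientCategory.MODERATE_NO_DME for c in cats)
    return 100 * mod / len(cats)


def eye_level_contingency(
    cohort: Sequence[PatientRecord], arm: Modality, round_index: int
) -> ContingencyTable:
    """Cross-classify gradable eyes by the arm's call vs the reference call.

    The unit of analysis is the eye; an eye enters only if both the reference
    standard and the arm grade it.
    """
    validate_arm(arm)
    tp = fp = tn = fn = 0
    for rec in cohort:
        grades = rec.grades(round_index)
        if grades is None or grades.reference is None:
            continue
        mod = grades.get(arm)
        if mod is None:
            continue
        for side in ("right_eye", "left_eye"):
            truth = eye_is_stdr(getattr(grades.reference, side))
            call = eye_is_stdr(getattr(mod, side))
            if truth is None or call is None:
                continue
            if truth and call:
                tp += 1
            elif truth:
                fn += 1
            elif call:
                fp += 1
            else:
                tn += 1
    return ContingencyTable(tp=tp, fp=fp, tn=tn, fn=fn)


def sample_size(prev: float, rel_margin: float = 0.10, alpha: float = 0.05) -> int:
    """Cohort size for estimating a prevalence to a *relative* margin of error.

    n = ceil( z^2 p (1 - p) / (rel_margin * p)^2 ), z the two-sided
    standard-normal quantile at level 1 - alpha.
    """
    if not 0 < prev < 1:
        raise ValueError("prevalence must be strictly between 0 and 1")
    if rel_margin <= 0:
        raise ValueError("relative margin must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    return math.ceil(z**2 * prev * (1 - prev) / (rel_margin * prev) ** 2)
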