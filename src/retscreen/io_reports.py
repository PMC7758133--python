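"""Cohort file formats, run summaries, and report tables.

Cohort CSV schema: one row per (patient, round, modality, eye), columns
``patient_id, round, modality, eye, dr_grade, dme, age, sex, hypertension,
fbs``.  Severity codes are ``none/mild/moderate/severe/pdr/ungradable``; DME
is ``0/1/ungradable``.  A modality with no rows for a round contributed no
data (missing); a patient with no round-2 rows at all has no follow-up.
UTF-8, comma-separated, header required.

Reports: ``analyze_cohort`` produces a JSON-ready run summary (every
percentage accompanied by its numerator and denominator), and
``render_reports`` writes four CSV tables from it: cohort characteristics,
screening metrics with between-round comparisons, contingency counts, and
severity-stratified progression.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .cohort import ARMS, Modality, ModalityGradeSet, PatientRecord
from .grading import (
    EyeAssessment,
    PatientAssessment,
    PatientCategory,
    GRADABLE_CATEGORIES,
    SEVERITY_CODES,
    SEVERITY_FROM_CODE,
    patient_category,
    stdr_subtype,
    StdrSubtype,
)
from .simulate import TwoRoundResult, run_two_round_study
from .synthcohort import GraderParams, SyntheticConfig

logger = logging.getLogger("retscreen")

COHORT_COLUMNS = [
    "patient_id",
    "round",
    "modality",
    "eye",
    "dr_grade",
    "dme",
    "age",
    "sex",
    "hypertension",
    "fbs",
]

_UNGRADABLE = "ungradable"


class CohortFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cohort CSV


def _eye_to_row(eye: EyeAssessment) -> Tuple[str, str]:
    if not eye.gradable:
        return _UNGRADABLE, _UNGRADABLE
    return SEVERITY_CODES[eye.dr], str(int(eye.dme))


def write_cohort(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Serialise a cohort to the standard patient-level CSV."""
    rows = []
    for rec in records:
        for rnd in (1, 2):
            grades = rec.grades(rnd)
            if grades is None:
                continue
            for modality in Modality:
                pa = grades.get(modality)
                if pa is None:
                    continue
                for eye_code, eye in (("R", pa.right_eye), ("L", pa.left_eye)):
                    dr, dme = _eye_to_row(eye)
                    rows.append(
                        (
                            rec.patient_id,
                            rnd,
                            modality.value,
                            eye_code,
                            dr,
                            dme,
                            rec.age,
                            rec.sex,
                            rec.hypertension,
                            rec.fbs,
                        )
                    )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def _parse_eye(dr_code: str, dme_code: str, row_no: int) -> EyeAssessment:
    if dr_code == _UNGRADABLE and dme_code == _UNGRADABLE:
        return EyeAssessment.ungradable()
    if dr_code == _UNGRADABLE or dme_code == _UNGRADABLE:
        raise CohortFormatError(
            f"row {row_no}: an eye is graded all-or-none "
            f"(dr_grade={dr_code!r}, dme={dme_code!r})"
        )
    if dr_code not in SEVERITY_FROM_CODE:
        raise CohortFormatError(
            f"row {row_no}: unknown dr_grade {dr_code!r} "
            f"(expected one of {sorted(SEVERITY_FROM_CODE)} or '{_UNGRADABLE}')"
        )
    if dme_code not in ("0", "1"):
        raise CohortFormatError(
            f"row {row_no}: unknown dme {dme_code!r} (expected 0, 1 or '{_UNGRADABLE}')"
        )
    return EyeAssessment(SEVERITY_FROM_CODE[dr_code], dme_code == "1")


def read_cohort(path: Union[str, Path]) -> List[PatientRecord]:
    """Read the patient-level CSV back into records.

    Malformed grade codes raise with the offending row number; patients
    lacking any of the three modalities at round 1 are dropped with a logged
    count; duplicate (patient, round, modality, eye) keys are an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"missing required columns: {missing_cols}")
    dup = df.duplicated(subset=["patient_id", "round", "modality", "eye"])
    if dup.any():
        first = df[dup].iloc[0]
        raise CohortFormatError(
            "duplicate key (patient_id, round, modality, eye): "
            f"{tuple(first[['patient_id', 'round', 'modality', 'eye']])}"
        )

    # eyes[(pid, round, modality)][eye] = EyeAssessment
    eyes: Dict[Tuple[str, int, Modality], Dict[str, EyeAssessment]] = {}
    demo: Dict[str, Tuple] = {}
    order: List[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rnd = int(row.round)
            modality = Modality(row.modality)
        except ValueError as exc:
            raise CohortFormatError(f"row {row_no}: {exc}") from None
        if rnd not in (1, 2):
            raise CohortFormatError(f"row {row_no}: round must be 1 or 2, got {rnd}")
        if row.eye not in ("R", "L"):
            raise CohortFormatError(f"row {row_no}: eye must be R or L, got {row.eye!r}")
        pid = row.patient_id
        if pid not in demo:
            order.append(pid)
            demo[pid] = (row.age, row.sex, row.hypertension, row.fbs)
        eyes.setdefault((pid, rnd, modality), {})[row.eye] = _parse_eye(
            row.dr_grade, row.dme, row_no
        )

    def _pa(pid: str, rnd: int, modality: Modality) -> Optional[PatientAssessment]:
        pair = eyes.get((pid, rnd, modality))
        if pair is None:
            return None
        # a single recorded eye implies the fellow photograph is missing
        return PatientAssessment(
            right_eye=pair.get("R", EyeAssessment.ungradable()),
            left_eye=pair.get("L", EyeAssessment.ungradable()),
        )

    records: List[PatientRecord] = []
    n_dropped = 0
    for pid in order:
        g1 = ModalityGradeSet(
            reference=_pa(pid, 1, Modality.REFERENCE),
            dl=_pa(pid, 1, Modality.DL),
            hg=_pa(pid, 1, Modality.HG),
        )
        if not g1.complete:
            n_dropped += 1
            continue
        g2 = ModalityGradeSet(
            reference=_pa(pid, 2, Modality.REFERENCE),
            dl=_pa(pid, 2, Modality.DL),
            hg=_pa(pid, 2, Modality.HG),
        )
        if g2.reference is None and g2.dl is None and g2.hg is None:
            g2 = None
        age, sex, htn, fbs = demo[pid]
        records.append(
            PatientRecord(
                patient_id=pid,
                round1=g1,
                round2=g2,
                age=float(age) if age else None,
                sex=sex or None,
                hypertension=int(htn) if htn else None,
                fbs=float(fbs) if fbs else None,
            )
        )
    if n_dropped:
        logger.warning(
            "dropped %d patient(s) lacking grades from all three modalities "
            "at the first screening",
            n_dropped,
        )
    return records


# ---------------------------------------------------------------------------
# synthetic-config serialisation (YAML/JSON)


def config_to_dict(config: SyntheticConfig) -> dict:
    return {
        "n_patients": config.n_patients,
        "baseline_probs": list(config.baseline_probs),
        "transition": [list(row) for row in config.transition],
        "graders": {
            arm.value: {
                "base_sens_dme": gp.base_sens_dme,
                "base_sens_sevpdr": gp.base_sens_sevpdr,
                "base_spec": gp.base_spec,
                "fp_moderate_boost": gp.fp_moderate_boost,
                "difficulty_weight": gp.difficulty_weight,
            }
            for arm, gp in config.graders.items()
        },
        "eye_concordance": config.eye_concordance,
        "ungradable_rate": config.ungradable_rate,
        "dropout_rate": config.dropout_rate,
        "incident_difficulty_boost": config.incident_difficulty_boost,
        "seed": config.seed,
    }


def config_from_dict(data: dict) -> SyntheticConfig:
    data = dict(data)
    graders = {
        Modality(arm): GraderParams(**params)
        for arm, params in data.pop("graders").items()
    }
    data["baseline_probs"] = tuple(data["baseline_probs"])
    data["transition"] = tuple(tuple(row) for row in data["transition"])
    return SyntheticConfig(graders=graders, **data)


def save_config(config: SyntheticConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: Union[str, Path]) -> SyntheticConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run summaries


def _metric_dict(result: M.MetricResult) -> dict:
    return {
        "estimate": result.estimate,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "numerator": result.numerator,
        "denominator": result.denominator,
    }


def _ref_categories(
    cohort: Sequence[PatientRecord], ids, round_index: int
) -> List[PatientCategory]:
    by_id = {r.patient_id: r for r in cohort}
    return [
        patient_category(by_id[i].grades(round_index).reference) for i in sorted(ids)
    ]


def _round_summary(outcome, cohort, ci_level: float) -> dict:
    ct = outcome.contingency
    cats_fn = _ref_categories(cohort, outcome.fn_ids, outcome.round_index)
    cats_fp = _ref_categories(cohort, outcome.fp_ids, outcome.round_index)
    cats_stdr = _ref_categories(
        cohort, outcome.tp_ids | outcome.fn_ids, outcome.round_index
    )
    summary = {
        "n_cohort": len(outcome.cohort_ids),
        "n_analyzed": len(outcome.analyzed_ids),
        "contingency": {"tp": ct.tp, "fp": ct.fp, "tn": ct.tn, "fn": ct.fn},
        "excluded": {k: len(v) for k, v in outcome.excluded.items()},
        "n_referred": len(outcome.referred_ids),
        "n_dropout": len(outcome.dropout_ids),
        "metrics": {
            name: _metric_dict(M.metric_from_table(name, ct, ci_level))
            for name in M.METRIC_NAMES
        },
        "breakdowns": {},
    }
    if cats_stdr:
        summary["breakdowns"]["stdr_dme_pct"] = M.stdr_breakdown(cats_stdr)[
            StdrSubtype.DME
        ]
    if cats_fn:
        summary["breakdowns"]["fn_dme_pct"] = M.stdr_breakdown(cats_fn)[
            StdrSubtype.DME
        ]
    if cats_fp:
        summary["breakdowns"]["fp_moderate_no_dme_pct"] = M.moderate_no_dme_fraction(
            cats_fp
        )
    return summary


def _cohort_characteristics(cohort: Sequence[PatientRecord], round_index: int) -> dict:
    ages = [r.age for r in cohort if r.age is not None]
    fbs = [r.fbs for r in cohort if r.fbs is not None]
    sexes = [r.sex for r in cohort if r.sex is not None]
    htn = [r.hypertension for r in cohort if r.hypertension is not None]
    cats = Counter(
        patient_category(r.grades(round_index).reference) for r in cohort
    )
    out = {
        "n": len(cohort),
        "age_mean": float(np.mean(ages)) if ages else None,
        "age_sd": float(np.std(ages, ddof=1)) if len(ages) > 1 else None,
        "female_n": sum(s == "F" for s in sexes),
        "hypertension_n": int(sum(htn)) if htn else 0,
        "fbs_mean": float(np.mean(fbs)) if fbs else None,
        "fbs_sd": float(np.std(fbs, ddof=1)) if len(fbs) > 1 else None,
        "categories": {c.value: cats.get(c, 0) for c in GRADABLE_CATEGORIES},
    }
    return out


def analyze_cohort(
    records: Sequence[PatientRecord],
    arms: Sequence[Modality] = ARMS,
    ci_level: float = 0.95,
) -> dict:
    """Run the two-round study for the requested arms and summarise
    everything into a JSON-ready dictionary."""
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    summary: dict = {"ci_level": ci_level, "n_records": len(records), "arms": {}}
    table1: dict = {}
    results: Dict[Modality, TwoRoundResult] = {}
    for arm in arms:
        res = run_two_round_study(records, arm)
        results[arm] = res
        arm_summary = {
            "n_study_excluded": len(res.study_excluded_ids),
            "round1": _round_summary(res.round1, res.cohort_round1, ci_level),
        }
        if res.round2 is not None:
            arm_summary["round2"] = _round_summary(
                res.round2, res.cohort_round2, ci_level
            )
            comparisons = {}
            for name in M.METRIC_NAMES:
                comp = M.compare_rounds(
                    name, res.round1.contingency, res.round2.contingency, ci_level
                )
                comparisons[name] = {
                    "difference": comp.difference,
                    "chi2": comp.chi2,
                    "p": comp.p,
                }
            arm_summary["comparisons"] = comparisons
            table1[f"{arm.value}_round2"] = _cohort_characteristics(
                res.cohort_round2, 2
            )
        else:
            logger.warning("arm %s: no patients left for a second screening", arm.value)
        summary["arms"][arm.value] = arm_summary
        if "round1" not in table1:
            table1["round1"] = _cohort_characteristics(res.cohort_round1, 1)
    summary["table1"] = table1
    summary["incidence"] = {
        source.value: M.incidence_by_baseline(records, detection_source=source)
        .reset_index()
        .to_dict(orient="records")
        for source in Modality
    }
    return summary


# ---------------------------------------------------------------------------
# report rendering


def _fmt_pct(num: int, den: int) -> str:
    return f"{num} ({100 * num / den:.2f}%)" if den else "0"


def render_reports(summary: dict, outdir: Union[str, Path]) -> List[Path]:
    """Write the four report tables (CSV) and the full summary (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    # characteristics table (sorted iteration keeps output byte-stable
    # regardless of summary dict ordering)
    rows = []
    for cohort_name, ch in sorted(summary.get("table1", {}).items()):
        row = {
            "cohort": cohort_name,
            "n": ch["n"],
            "age_mean": ch["age_mean"],
            "age_sd": ch["age_sd"],
            "female_n": ch["female_n"],
            "female_pct": 100 * ch["female_n"] / ch["n"] if ch["n"] else None,
            "hypertension_n": ch["hypertension_n"],
            "fbs_mean": ch["fbs_mean"],
            "fbs_sd": ch["fbs_sd"],
        }
        for cat, count in sorted(ch["categories"].items()):
            row[f"{cat}_n"] = count
            row[f"{cat}_pct"] = 100 * count / ch["n"] if ch["n"] else None
        rows.append(row)
    p = outdir / "table_characteristics.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    # screening metrics with comparisons
    rows = []
    for arm, arm_summary in sorted(summary["arms"].items()):
        for name in M.METRIC_NAMES:
            m1 = arm_summary["round1"]["metrics"][name]
            row = {
                "arm": arm,
                "metric": name,
                "round1_estimate": round(m1["estimate"], 2),
                "round1_ci": f"{m1['ci_low']:.2f}-{m1['ci_high']:.2f}",
                "round1_fraction": f"{m1['numerator']}/{m1['denominator']}",
            }
            if "round2" in arm_summary:
                m2 = arm_summary["round2"]["metrics"][name]
                comp = arm_summary["comparisons"][name]
                row.update(
                    {
                        "round2_estimate": round(m2["estimate"], 2),
                        "round2_ci": f"{m2['ci_low']:.2f}-{m2['ci_high']:.2f}",
                        "round2_fraction": f"{m2['numerator']}/{m2['denominator']}",
                        "difference": round(comp["difference"], 2),
                        "p": comp["p"],
                    }
                )
            else:
                row["round2_estimate"] = "absent"
            rows.append(row)
    p = outdir / "table_metrics.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    # contingency counts
    rows = []
    for arm, arm_summary in sorted(summary["arms"].items()):
        for rnd in ("round1", "round2"):
            if rnd not in arm_summary:
                continue
            ct = arm_summary[rnd]["contingency"]
            n = sum(ct.values())
            rows.append(
                {
                    "arm": arm,
                    "round": rnd,
                    "n": n,
                    **{
                        f"{cell}": _fmt_pct(ct[cell], n)
                        for cell in ("tp", "fp", "tn", "fn")
                    },
                }
            )
    p = outdir / "table_contingency.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    # progression / incidence
    rows = []
    for source, table in sorted(summary["incidence"].items()):
        for entry in table:
            rows.append({"detection_source": source, **entry})
    p = outdir / "table_progression.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    p = outdir / "run_summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(p)
    return written


def plot_round_trends(summary: dict, path: Union[str, Path]) -> None:
    """A small prevalence / sensitivity by-round chart (one panel per arm)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arms = list(summary["arms"])
    fig, axes = plt.subplots(1, len(arms), figsize=(4 * len(arms), 3), squeeze=False)
    for ax, arm in zip(axes[0], arms):
        arm_summary = summary["arms"][arm]
        rounds = [r for r in ("round1", "round2") if r in arm_summary]
        xs = list(range(1, len(rounds) + 1))
        for name, marker in (("prevalence", "o"), ("sensitivity", "s")):
            ys = [arm_summary[r]["metrics"][name]["estimate"] for r in rounds]
            ax.plot(xs, ys, marker=marker, label=name)
        ax.set_xticks(xs)
        ax.set_xlabel("screening round")
        ax.set_ylabel("%")
        ax.set_title(arm.upper())
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
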