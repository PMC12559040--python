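"""The adapted 2016 ASE/EACVI decision tree for diastolic dysfunction.

The tree has two steps. The *diagnosis* step applies four criteria
(average E/e' > cutoff; septal or lateral e' below its cutoff; elevated
pulmonary arterial pressure — TR for echo, t_vortex for 4D flow;
enlarged left atrium) and classifies by majority over the *available*
criteria. The *grading* step first separates impaired relaxation
(E/A <= 0.8 with E <= 50 cm/s -> grade I) and restrictive filling
(E/A >= 2.0 -> grade III), then grades the pseudonormal middle range by
a three-criterion majority (E/e', pulmonary pressure, left atrium).

Subjects with depressed EF or known structural myocardial disease enter
the grading step directly; all others pass through the diagnosis step
first. All threshold comparisons are strict, exactly as printed (a value
equal to a cutoff is on the non-positive side).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .core import (DiastolicGrade, GradingCutoffs, ModalityMeasurements,
                   SubjectRecord)

__all__ = [
    "CriterionStatus",
    "Diagnosis",
    "GradingError",
    "GradingDetail",
    "evaluate_diagnosis_criteria",
    "evaluate_grading_criteria",
    "diagnose",
    "grade_dysfunction",
    "grade_subject",
    "grade_subject_detailed",
]


class CriterionStatus(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNAVAILABLE = "unavailable"


class Diagnosis(enum.Enum):
    NORMAL = "normal"
    INDETERMINATE = "indeterminate"
    DYSFUNCTION = "dysfunction"


class GradingError(ValueError):
    """A measurement required by the decision tree is undefined."""


DIAGNOSIS_CRITERIA = ("avg_E_over_eprime", "reduced_eprime",
                      "elevated_pa_pressure", "enlarged_la")
GRADING_CRITERIA = ("avg_E_over_eprime", "elevated_pa_pressure", "enlarged_la")

_POS = CriterionStatus.POSITIVE
_NEG = CriterionStatus.NEGATIVE
_UNAVAIL = CriterionStatus.UNAVAILABLE


def _strict(value: Optional[float], cutoff: float, above: bool) -> CriterionStatus:
    if value is None:
        return _UNAVAIL
    hit = value > cutoff if above else value < cutoff
    return _POS if hit else _NEG


def _pa_pressure_criterion(m: ModalityMeasurements,
                           c: GradingCutoffs) -> CriterionStatus:
    """Elevated pulmonary arterial pressure: TR (echo) or t_vortex (4D flow).

    Echo TR absent -> unavailable (non-detectable regurgitation carries no
    information for this criterion). 4D-flow t_vortex is always acquired;
    its absence is a data error, not an unavailable criterion.
    """
    if c.modality == "echo":
        return _strict(m.tr_peak, c.tr_high, above=True)
    if m.t_vortex is None:
        raise GradingError("t_vortex is required for 4D flow grading")
    return _strict(m.t_vortex, c.tvortex_high, above=True)


def evaluate_diagnosis_criteria(m: ModalityMeasurements,
                                c: GradingCutoffs) -> dict[str, CriterionStatus]:
    """Evaluate the four diagnosis-step criteria. All comparisons strict."""
    if m.e_peak is None:
        raise GradingError("transmitral E peak velocity is required")
    if m.e_prime_septal is None and m.e_prime_lateral is None:
        raise GradingError("at least one e' velocity is required")
    reduced = _NEG
    if (m.e_prime_septal is not None and m.e_prime_septal < c.e_prime_septal_low) or \
       (m.e_prime_lateral is not None and m.e_prime_lateral < c.e_prime_lateral_low):
        reduced = _POS
    return {
        "avg_E_over_eprime": _strict(m.e_over_eprime, c.e_over_eprime_high, above=True),
        "reduced_eprime": reduced,
        "elevated_pa_pressure": _pa_pressure_criterion(m, c),
        "enlarged_la": _strict(m.lavi, c.lavi_high, above=True),
    }


def evaluate_grading_criteria(m: ModalityMeasurements,
                              c: GradingCutoffs) -> dict[str, CriterionStatus]:
    """The three grading-step criteria (no reduced-e' entry)."""
    return {
        "avg_E_over_eprime": _strict(m.e_over_eprime, c.e_over_eprime_high, above=True),
        "elevated_pa_pressure": _pa_pressure_criterion(m, c),
        "enlarged_la": _strict(m.lavi, c.lavi_high, above=True),
    }


def diagnose(criteria: dict[str, CriterionStatus]) -> Diagnosis:
    """Majority rule over the available criteria.

    More than half positive -> dysfunction; exactly half -> indeterminate;
    fewer than half -> normal. Requires at least two available criteria.
    """
    available = [s for s in criteria.values() if s is not _UNAVAIL]
    if len(available) < 2:
        raise GradingError(
            f"diagnosis requires >= 2 available criteria, got {len(available)}")
    n_pos = sum(s is _POS for s in available)
    if 2 * n_pos > len(available):
        return Diagnosis.DYSFUNCTION
    if 2 * n_pos == len(available):
        return Diagnosis.INDETERMINATE
    return Diagnosis.NORMAL


def grade_dysfunction(m: ModalityMeasurements, c: GradingCutoffs) -> DiastolicGrade:
    """Grading step for subjects with (suspected) diastolic dysfunction.

    E/A <= ea_low with E <= e_high -> grade I (impaired relaxation);
    E/A >= ea_high -> grade III (restrictive filling); otherwise a
    three-criterion majority decides grade II vs grade I, with an even
    split (or fewer than two available criteria) left indeterminate.
    """
    ea = m.e_over_a
    if ea is None:
        raise GradingError(
            "E/A ratio undefined (A peak absent or zero); cannot grade")
    if ea <= c.ea_low and m.e_peak <= c.e_high:
        return DiastolicGrade.GRADE1
    if ea >= c.ea_high:
        return DiastolicGrade.GRADE3
    crit = evaluate_grading_criteria(m, c)
    n_pos = sum(s is _POS for s in crit.values())
    n_neg = sum(s is _NEG for s in crit.values())
    if n_pos >= 2:
        return DiastolicGrade.GRADE2
    if n_neg >= 2:
        return DiastolicGrade.GRADE1
    return DiastolicGrade.INDETERMINATE


@dataclass(frozen=True)
class GradingDetail:
    """Audit record of one subject's path through the decision tree."""

    grade: DiastolicGrade
    route: str                      # "depressed_ef", "myocardial_disease", "diagnosis"
    diagnosis: Optional[Diagnosis]  # None when the diagnosis step was bypassed
    diagnosis_criteria: Optional[dict[str, CriterionStatus]]
    grading_criteria: Optional[dict[str, CriterionStatus]]


def grade_subject_detailed(record: SubjectRecord, modality: str,
                           cutoffs: GradingCutoffs) -> GradingDetail:
    """Full decision-tree pass with the evaluated criterion statuses."""
    if modality == "echo":
        m = record.echo
    elif modality == "flow4d":
        m = record.flow4d
    else:
        raise ValueError(f"unknown modality: {modality!r}")
    if cutoffs.modality != modality:
        raise ValueError(
            f"cutoffs are for {cutoffs.modality!r}, requested {modality!r}")

    if m.ef < cutoffs.ef_low or record.myocardial_disease:
        route = "depressed_ef" if m.ef < cutoffs.ef_low else "myocardial_disease"
        grading_crit = None
        grade = grade_dysfunction(m, cutoffs)
        if grade in (DiastolicGrade.GRADE2, DiastolicGrade.GRADE1,
                     DiastolicGrade.INDETERMINATE):
            grading_crit = evaluate_grading_criteria(m, cutoffs)
        return GradingDetail(grade, route, None, None, grading_crit)

    diag_crit = evaluate_diagnosis_criteria(m, cutoffs)
    diag = diagnose(diag_crit)
    if diag is Diagnosis.NORMAL:
        return GradingDetail(DiastolicGrade.NORMAL, "diagnosis", diag,
                             diag_crit, None)
    if diag is Diagnosis.INDETERMINATE:
        return GradingDetail(DiastolicGrade.INDETERMINATE, "diagnosis", diag,
                             diag_crit, None)
    grade = grade_dysfunction(m, cutoffs)
    # Dysfunction was already established by the diagnosis majority, so an
    # even grading split still means dysfunction of at least grade I.
    grade = max(grade, DiastolicGrade.GRADE1)
    grading_crit = evaluate_grading_criteria(m, cutoffs)
    return GradingDetail(grade, "diagnosis", diag, diag_crit, grading_crit)


def grade_subject(record: SubjectRecord, modality: str,
                  cutoffs: GradingCutoffs) -> DiastolicGrade:
    """Grade one subject with one modality's measurements and cutoffs."""
    return grade_subject_detailed(record, modality, cutoffs).grade
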