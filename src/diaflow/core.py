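"""Domain types, unit conventions, validation and file round-tripping.

Units are fixed per field and never converted implicitly: EF and t_vortex
in percent, LAVI in mL/m^2, transmitral (E, A) and myocardial (e') peak
velocities in cm/s, tricuspid regurgitant peak velocity (TR) in m/s.
Missing values are explicit ``None``, never sentinel numbers — an absent
echo TR means the regurgitant jet was not detectable, which is clinically
meaningful and handled as such downstream.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

__all__ = [
    "DiastolicGrade",
    "ModalityMeasurements",
    "SubjectRecord",
    "GradingCutoffs",
    "Violation",
    "validate_record",
    "default_cutoffs",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "frame_to_records",
    "read_cutoffs",
    "write_cutoffs",
    "COHORT_COLUMNS",
]


class DiastolicGrade(enum.IntEnum):
    """Ordinal diastolic-function outcome.

    Order: normal(0) < indeterminate < grade1 < grade2 < grade3, i.e. the
    indeterminate category sits between normal function and grade I, the
    category order used when cross-tabulating two graders.
    """

    NORMAL = 0
    INDETERMINATE = 1
    GRADE1 = 2
    GRADE2 = 3
    GRADE3 = 4

    @property
    def label(self) -> str:
        return _GRADE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "DiastolicGrade":
        try:
            return _LABEL_TO_GRADE[str(label).strip().lower()]
        except KeyError:
            raise ValueError(f"unknown diastolic grade label: {label!r}") from None


_GRADE_LABELS = {
    DiastolicGrade.NORMAL: "0",
    DiastolicGrade.INDETERMINATE: "indet",
    DiastolicGrade.GRADE1: "1",
    DiastolicGrade.GRADE2: "2",
    DiastolicGrade.GRADE3: "3",
}
_LABEL_TO_GRADE = {v: k for k, v in _GRADE_LABELS.items()}
_LABEL_TO_GRADE.update({"normal": DiastolicGrade.NORMAL,
                        "indeterminate": DiastolicGrade.INDETERMINATE,
                        "grade1": DiastolicGrade.GRADE1,
                        "grade2": DiastolicGrade.GRADE2,
                        "grade3": DiastolicGrade.GRADE3})

GRADE_ORDER: tuple[DiastolicGrade, ...] = tuple(DiastolicGrade)


@dataclass(frozen=True)
class ModalityMeasurements:
    """One modality's hemodynamic parameter set for a single subject.

    ``tr_peak`` is echo-only (continuous-wave Doppler) and may be absent
    when no tricuspid regurgitant jet is detectable; ``t_vortex`` — the
    duration of vortical blood flow along the main pulmonary artery as a
    percentage of the cardiac interval — is the 4D-flow surrogate for it.
    """

    ef: float                                # LV ejection fraction, %
    lavi: float                              # max LA volume index, mL/m^2
    e_peak: float                            # transmitral early peak, cm/s
    a_peak: Optional[float] = None           # transmitral late peak, cm/s
    e_prime_septal: Optional[float] = None   # septal e', cm/s
    e_prime_lateral: Optional[float] = None  # lateral e', cm/s
    tr_peak: Optional[float] = None          # TR peak velocity, m/s
    t_vortex: Optional[float] = None         # vortex duration, % of interval

    @property
    def e_over_a(self) -> Optional[float]:
        """E/A ratio; undefined (None) when A is absent or zero."""
        if self.a_peak is None or self.a_peak <= 0:
            return None
        return self.e_peak / self.a_peak

    @property
    def e_prime_avg(self) -> Optional[float]:
        """Average of septal and lateral e' (mean of whichever are present)."""
        vals = [v for v in (self.e_prime_septal, self.e_prime_lateral) if v is not None]
        if not vals:
            return None
        return sum(vals) / len(vals)

    @property
    def e_over_eprime(self) -> Optional[float]:
        """E/e' using the average e'; None when no e' is available."""
        avg = self.e_prime_avg
        if avg is None or avg <= 0:
            return None
        return self.e_peak / avg


@dataclass(frozen=True)
class SubjectRecord:
    """Paired echo and 4D-flow measurements for one subject.

    ``myocardial_disease`` flags structural heart disease, which routes
    the subject directly into the grading branch of the decision tree.
    ``true_grade`` is carried only by synthetic cohorts (the intended
    grade used in recovery tests).
    """

    subject_id: str
    echo: ModalityMeasurements
    flow4d: ModalityMeasurements
    myocardial_disease: bool = False
    true_grade: Optional[DiastolicGrade] = None


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


def _check_measurements(m: ModalityMeasurements, prefix: str,
                        require_tvortex: bool) -> list[Violation]:
    out: list[Violation] = []
    if not (0 <= m.ef <= 100):
        out.append(Violation(f"{prefix}.ef", "EF must be in [0, 100] %"))
    if not (m.lavi > 0):
        out.append(Violation(f"{prefix}.lavi", "LAVI must be > 0 mL/m^2"))
    for name in ("e_peak", "a_peak", "e_prime_septal", "e_prime_lateral", "tr_peak"):
        v = getattr(m, name)
        if v is not None and v < 0:
            out.append(Violation(f"{prefix}.{name}", "velocity must be >= 0"))
    if m.t_vortex is not None and not (0 <= m.t_vortex <= 100):
        out.append(Violation(f"{prefix}.t_vortex", "t_vortex must be in [0, 100] %"))
    if require_tvortex and m.t_vortex is None:
        out.append(Violation(f"{prefix}.t_vortex",
                             "t_vortex is required for 4D flow records"))
    return out


def validate_record(record: SubjectRecord) -> list[Violation]:
    """Check all type invariants; violations are returned as data, never raised.

    An absent echo TR is legal (non-detectable tricuspid regurgitation);
    an absent 4D-flow t_vortex is a violation.
    """
    out: list[Violation] = []
    if not str(record.subject_id).strip():
        out.append(Violation("subject_id", "subject_id must be non-empty"))
    out += _check_measurements(record.echo, "echo", require_tvortex=False)
    out += _check_measurements(record.flow4d, "flow4d", require_tvortex=True)
    return out


@dataclass(frozen=True)
class GradingCutoffs:
    """The complete threshold set of the decision tree for one modality.

    The echo defaults are the established 2016 ASE/EACVI cutoffs; the
    4D-flow defaults replace EF and LAVI by their bias-adjusted values
    (55 %, 47 mL/m^2) and the TR criterion by the vortex-duration
    surrogate (t_vortex > 15 %). Exactly one of ``tr_high`` /
    ``tvortex_high`` is populated, matching the modality tag.
    """

    modality: str                      # "echo" or "flow4d"
    ef_low: float                      # depressed-EF routing threshold, %
    lavi_high: float                   # enlarged-LA threshold, mL/m^2
    e_high: float                      # E threshold, cm/s
    ea_low: float                      # lower E/A threshold
    ea_high: float                     # upper E/A threshold
    e_prime_septal_low: float          # septal e' threshold, cm/s
    e_prime_lateral_low: float         # lateral e' threshold, cm/s
    e_over_eprime_high: float          # average E/e' threshold
    tr_high: Optional[float] = None    # TR threshold, m/s (echo)
    tvortex_high: Optional[float] = None  # t_vortex threshold, % (4D flow)

    def __post_init__(self) -> None:
        if self.modality not in ("echo", "flow4d"):
            raise ValueError(f"unknown modality tag: {self.modality!r}")
        if not self.ea_low < self.ea_high:
            raise ValueError("ea_low must be < ea_high")
        for name in ("ef_low", "lavi_high", "e_high", "ea_low", "ea_high",
                     "e_prime_septal_low", "e_prime_lateral_low",
                     "e_over_eprime_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.modality == "echo":
            if self.tr_high is None or self.tvortex_high is not None:
                raise ValueError("echo cutoffs carry tr_high only")
        else:
            if self.tvortex_high is None or self.tr_high is not None:
                raise ValueError("flow4d cutoffs carry tvortex_high only")


def default_cutoffs(modality: str) -> GradingCutoffs:
    """Default threshold set per modality.

    echo: EF 50 %, LAVI 34 mL/m^2, E 50 cm/s, E/A 0.8 and 2.0, septal e'
    7 cm/s, lateral e' 10 cm/s, E/e' 14, TR 2.8 m/s.
    flow4d: identical velocity thresholds with the bias-adjusted EF 55 %,
    LAVI 47 mL/m^2, and the surrogate t_vortex 15 %.
    """
    common = dict(e_high=50.0, ea_low=0.8, ea_high=2.0,
                  e_prime_septal_low=7.0, e_prime_lateral_low=10.0,
                  e_over_eprime_high=14.0)
    if modality == "echo":
        return GradingCutoffs(modality="echo", ef_low=50.0, lavi_high=34.0,
                              tr_high=2.8, **common)
    if modality == "flow4d":
        return GradingCutoffs(modality="flow4d", ef_low=55.0, lavi_high=47.0,
                              tvortex_high=15.0, **common)
    raise ValueError(f"unknown modality tag: {modality!r}")


# ---------------------------------------------------------------------------
# Cohort CSV round-tripping
# ---------------------------------------------------------------------------
# One row per subject; empty cell = missing. Comma-separated, UTF-8,
# "." decimal, header required.

COHORT_COLUMNS = [
    "subject_id", "myocardial_disease",
    "echo_ef", "echo_lavi", "echo_e", "echo_a",
    "echo_e_prime_septal", "echo_e_prime_lateral", "echo_tr",
    "flow_ef", "flow_lavi", "flow_e", "flow_a",
    "flow_e_prime_septal", "flow_e_prime_lateral", "flow_t_vortex",
    "true_grade",
]

_ECHO_FIELDS = {"echo_ef": "ef", "echo_lavi": "lavi", "echo_e": "e_peak",
                "echo_a": "a_peak", "echo_e_prime_septal": "e_prime_septal",
                "echo_e_prime_lateral": "e_prime_lateral", "echo_tr": "tr_peak"}
_FLOW_FIELDS = {"flow_ef": "ef", "flow_lavi": "lavi", "flow_e": "e_peak",
                "flow_a": "a_peak", "flow_e_prime_septal": "e_prime_septal",
                "flow_e_prime_lateral": "e_prime_lateral",
                "flow_t_vortex": "t_vortex"}


def _parse_cell(cell: Optional[str]) -> Optional[float]:
    if cell is None or str(cell).strip() == "":
        return None
    return float(cell)


def _parse_bool(cell: str) -> bool:
    s = str(cell).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no", ""):
        return False
    raise ValueError(f"cannot parse boolean cell: {cell!r}")


def _row_to_record(row: dict) -> SubjectRecord:
    echo_kw = {f: _parse_cell(row.get(col)) for col, f in _ECHO_FIELDS.items()}
    flow_kw = {f: _parse_cell(row.get(col)) for col, f in _FLOW_FIELDS.items()}
    for kw, side in ((echo_kw, "echo"), (flow_kw, "flow")):
        for required in ("ef", "lavi", "e_peak"):
            if kw[required] is None:
                raise ValueError(
                    f"subject {row.get('subject_id')!r}: missing required "
                    f"{side} field {required}")
    tg = row.get("true_grade")
    grade = DiastolicGrade.from_label(tg) if tg not in (None, "") else None
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        myocardial_disease=_parse_bool(row.get("myocardial_disease", "")),
        echo=ModalityMeasurements(**echo_kw),
        flow4d=ModalityMeasurements(**flow_kw),
        true_grade=grade,
    )


def _fmt(v: Optional[float]) -> str:
    if v is None:
        return ""
    # fixed precision so re-runs with the same seed are byte-identical
    return format(float(v), ".4f")


def _record_to_row(r: SubjectRecord) -> dict:
    row = {"subject_id": r.subject_id,
           "myocardial_disease": "1" if r.myocardial_disease else "0",
           "true_grade": r.true_grade.label if r.true_grade is not None else ""}
    for col, f in _ECHO_FIELDS.items():
        row[col] = _fmt(getattr(r.echo, f))
    for col, f in _FLOW_FIELDS.items():
        row[col] = _fmt(getattr(r.flow4d, f))
    return row


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV; raises on missing header or duplicate subject ids."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "subject_id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing header with subject_id column")
        records = [_row_to_record(row) for row in reader]
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id values: {dupes}")
    return records


def write_cohort_csv(records: Sequence[SubjectRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COHORT_COLUMNS)
        writer.writeheader()
        for r in records:
            writer.writerow(_record_to_row(r))


def records_to_frame(records: Sequence[SubjectRecord]):
    """Cohort as a pandas DataFrame in the CSV column layout (NaN = missing)."""
    import pandas as pd

    rows = []
    for r in records:
        row: dict = {"subject_id": r.subject_id,
                     "myocardial_disease": r.myocardial_disease,
                     "true_grade": r.true_grade.label if r.true_grade else None}
        for col, f in _ECHO_FIELDS.items():
            row[col] = getattr(r.echo, f)
        for col, f in _FLOW_FIELDS.items():
            row[col] = getattr(r.flow4d, f)
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(frame) -> list[SubjectRecord]:
    import math

    def clean(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    records = []
    for _, row in frame.iterrows():
        d = {c: clean(row.get(c)) for c in frame.columns}
        d = {k: ("" if v is None else v) for k, v in d.items()}
        records.append(_row_to_record(d))
    return records


# ---------------------------------------------------------------------------
# Cutoff config round-tripping (flat YAML/JSON mirroring GradingCutoffs)
# ---------------------------------------------------------------------------

def write_cutoffs(cutoffs: GradingCutoffs, path: str | Path) -> None:
    data = {f.name: getattr(cutoffs, f.name) for f in fields(cutoffs)}
    data = {k: v for k, v in data.items() if v is not None}
    text = (json.dumps(data, indent=2, sort_keys=True) + "\n"
            if str(path).endswith(".json") else
            yaml.safe_dump(data, sort_keys=True))
    Path(path).write_text(text, encoding="utf-8")


def read_cutoffs(path: str | Path) -> GradingCutoffs:
    text = Path(path).read_text(encoding="utf-8")
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of cutoff fields")
    known = {f.name for f in fields(GradingCutoffs)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown cutoff fields {sorted(unknown)}")
    return GradingCutoffs(**data)
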