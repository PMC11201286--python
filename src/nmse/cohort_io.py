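"""Cohort container and the cohort CSV interchange format.

The CSV schema is deliberately spreadsheet-friendly (the original E-score
calculator was an Excel sheet): UTF-8, comma separators, a required header,
booleans as 0/1, cm fields to one decimal place, semicolon-separated lists
inside a cell, empty cells for missing outcomes.

Ingestion is lenient by default: rows that violate an exam invariant are
reported (row number + messages) and skipped while the remaining rows load;
``strict=True`` aborts on the first bad row instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .exam import (
    ADHESION_SITES,
    AdhesionMap,
    CystKind,
    OvarySideFinding,
    Outcomes,
    PainMap,
    PAIN_REGION_NUMERALS,
    PatientExam,
    RareSiteFindings,
    TubalLesion,
    UterineFindings,
    validate_exam,
)

__all__ = [
    "Cohort",
    "RowIssue",
    "CohortSchemaError",
    "CohortRowError",
    "COHORT_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "exam_to_row",
    "row_to_exam",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "right_cyst_cm",
    "right_cyst_kind",
    "right_tubal",
    "left_cyst_cm",
    "left_cyst_kind",
    "left_tubal",
    *ADHESION_SITES,
    *(f"pain_{n}" for n in PAIN_REGION_NUMERALS),
    "ut_retroverted",
    "ut_adenomyosis",
    "ut_nodules_cm",
    "ut_myoma",
    "rare_sites",
    "duration_min",
    "blood_loss_ml",
    "rasrm_score",
)


class CohortSchemaError(ValueError):
    """The CSV header does not match the cohort schema."""


class CohortRowError(ValueError):
    """A row failed validation in strict mode."""


@dataclass(frozen=True)
class RowIssue:
    row: int  # 1-based data-row number (header excluded)
    patient_id: str
    messages: tuple[str, ...]


@dataclass
class Cohort:
    """An ordered collection of patient exams, the unit of correlation analysis."""

    exams: list[PatientExam] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    ingest_issues: list[RowIssue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.exams)

    def __iter__(self) -> Iterator[PatientExam]:
        return iter(self.exams)

    def __getitem__(self, i: int) -> PatientExam:
        return self.exams[i]

    def outcome_values(self, name: str) -> list[Optional[float]]:
        """Column of one outcome ('duration_min', 'blood_loss_ml', 'rasrm_score')."""
        if name not in ("duration_min", "blood_loss_ml", "rasrm_score"):
            raise KeyError(f"unknown outcome {name!r}")
        return [
            getattr(e.outcomes, name) if e.outcomes is not None else None
            for e in self.exams
        ]


def _kind_str(kind: CystKind, label: Optional[str]) -> str:
    if kind == CystKind.OTHER:
        return f"other:{label}"
    return kind.value


def _tubal_str(lesion: TubalLesion, label: Optional[str]) -> str:
    if lesion == TubalLesion.OTHER:
        return f"other:{label}"
    return lesion.value


def _parse_kind(text: str) -> tuple[CystKind, Optional[str]]:
    if text.startswith("other:"):
        return CystKind.OTHER, text[6:]
    return CystKind(text), None


def _parse_tubal(text: str) -> tuple[TubalLesion, Optional[str]]:
    if text.startswith("other:"):
        return TubalLesion.OTHER, text[6:]
    return TubalLesion(text), None


def _num(x: float) -> str:
    """Shortest round-tripping decimal for an outcome number."""
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def exam_to_row(exam: PatientExam) -> dict[str, str]:
    """Serialize one exam to a dict of schema-column -> cell text."""
    row: dict[str, str] = {
        "patient_id": exam.patient_id,
        "right_cyst_cm": f"{exam.right.cyst_diameter_cm:.1f}",
        "right_cyst_kind": _kind_str(exam.right.cyst_kind, exam.right.cyst_label),
        "right_tubal": _tubal_str(exam.right.tubal_lesion, exam.right.tubal_label),
        "left_cyst_cm": f"{exam.left.cyst_diameter_cm:.1f}",
        "left_cyst_kind": _kind_str(exam.left.cyst_kind, exam.left.cyst_label),
        "left_tubal": _tubal_str(exam.left.tubal_lesion, exam.left.tubal_label),
    }
    for site in ADHESION_SITES:
        row[site] = "1" if exam.adhesions.sites.get(site, False) else "0"
    for numeral in PAIN_REGION_NUMERALS:
        row[f"pain_{numeral}"] = str(exam.pain.values.get(numeral, 0))
    row["ut_retroverted"] = "1" if exam.uterus.retroverted else "0"
    row["ut_adenomyosis"] = "1" if exam.uterus.adenomyosis else "0"
    row["ut_nodules_cm"] = ";".join(f"{d:.1f}" for d in exam.uterus.nodules_cm)
    row["ut_myoma"] = "1" if exam.uterus.myoma else "0"
    row["rare_sites"] = ";".join(exam.rare.ordered())
    o = exam.outcomes or Outcomes()
    row["duration_min"] = "" if o.duration_min is None else _num(o.duration_min)
    row["blood_loss_ml"] = "" if o.blood_loss_ml is None else _num(o.blood_loss_ml)
    row["rasrm_score"] = "" if o.rasrm_score is None else str(int(o.rasrm_score))
    return row


def _bool_cell(text: str, column: str) -> bool:
    if text not in ("0", "1"):
        raise ValueError(f"{column}: boolean cell must be 0 or 1, got {text!r}")
    return text == "1"


def row_to_exam(row: dict[str, str]) -> PatientExam:
    """Deserialize one schema row; raises ValueError on unparseable cells."""
    r_kind, r_label = _parse_kind(row["right_cyst_kind"])
    l_kind, l_label = _parse_kind(row["left_cyst_kind"])
    r_tub, r_tlab = _parse_tubal(row["right_tubal"])
    l_tub, l_tlab = _parse_tubal(row["left_tubal"])
    right = OvarySideFinding(
        side="right",
        cyst_diameter_cm=float(row["right_cyst_cm"]),
        cyst_kind=r_kind,
        cyst_label=r_label,
        tubal_lesion=r_tub,
        tubal_label=r_tlab,
    )
    left = OvarySideFinding(
        side="left",
        cyst_diameter_cm=float(row["left_cyst_cm"]),
        cyst_kind=l_kind,
        cyst_label=l_label,
        tubal_lesion=l_tub,
        tubal_label=l_tlab,
    )
    adhesions = AdhesionMap(
        {site: _bool_cell(row[site], site) for site in ADHESION_SITES}
    )
    pain = PainMap({n: int(row[f"pain_{n}"]) for n in PAIN_REGION_NUMERALS})
    nodules = tuple(
        float(d) for d in row["ut_nodules_cm"].split(";") if d.strip()
    )
    uterus = UterineFindings(
        retroverted=_bool_cell(row["ut_retroverted"], "ut_retroverted"),
        adenomyosis=_bool_cell(row["ut_adenomyosis"], "ut_adenomyosis"),
        nodules_cm=nodules,
        myoma=_bool_cell(row["ut_myoma"], "ut_myoma"),
    )
    rare = RareSiteFindings(
        frozenset(s for s in row["rare_sites"].split(";") if s.strip())
    )
    outcomes = None
    if row["duration_min"] or row["blood_loss_ml"] or row["rasrm_score"]:
        outcomes = Outcomes(
            duration_min=float(row["duration_min"]) if row["duration_min"] else None,
            blood_loss_ml=float(row["blood_loss_ml"]) if row["blood_loss_ml"] else None,
            rasrm_score=int(row["rasrm_score"]) if row["rasrm_score"] else None,
        )
    return PatientExam(
        patient_id=row["patient_id"],
        right=right,
        left=left,
        adhesions=adhesions,
        pain=pain,
        uterus=uterus,
        rare=rare,
        outcomes=outcomes,
    )


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical schema (write∘read = identity)."""
    frame = pd.DataFrame(
        [exam_to_row(e) for e in cohort.exams], columns=list(COHORT_COLUMNS), dtype=str
    )
    frame.to_csv(path, index=False)


def read_cohort_csv(path: str | Path, strict: bool = False) -> Cohort:
    """Read a cohort CSV.

    Lenient mode (default) loads every valid row, records a
    :class:`RowIssue` per invalid one on ``cohort.ingest_issues`` and logs it;
    ``strict=True`` raises :class:`CohortRowError` at the first bad row.
    A header that does not match the schema raises :class:`CohortSchemaError`
    naming the missing/unexpected columns.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing columns: {missing}")
    unexpected = [c for c in frame.columns if c not in COHORT_COLUMNS]
    if unexpected:
        raise CohortSchemaError(f"unexpected columns: {unexpected}")

    cohort = Cohort(provenance={"source": str(path)})
    for i, row in enumerate(frame.to_dict(orient="records"), start=1):
        pid = row.get("patient_id", "")
        try:
            exam = row_to_exam(row)
            messages = validate_exam(exam)
        except (ValueError, KeyError) as exc:
            exam, messages = None, [str(exc)]
        if messages:
            issue = RowIssue(row=i, patient_id=pid, messages=tuple(messages))
            if strict:
                raise CohortRowError(
                    f"row {i} (patient {pid!r}): " + "; ".join(messages)
                )
            logger.warning("skipping row %d (patient %r): %s", i, pid, "; ".join(messages))
            cohort.ingest_issues.append(issue)
            continue
        cohort.exams.append(exam)
    return cohort
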