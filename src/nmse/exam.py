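"""Domain model for a single NMS-E examination.

The Numerical Multi-Scoring System of Endometriosis (NMS-E) records, for one
patient, the findings of a transvaginal ultrasound plus pelvic examination on a
*Physical Finding Map*: ovarian cysts and tubal lesions per side, the sliding
sign at ten adhesion sites, palpation pain (NRS 0-10) in seven pelvic regions
around the cervix, uterine lesions (retroversion R, adenomyosis A,
endometriotic nodules E >= 1 cm, myoma M), and rare-site disease.

These types hold raw findings only; scores are computed in :mod:`nmse.scoring`.
Validation is deliberately non-throwing (:func:`validate_exam` returns a list
of violation messages) so that messy rows read from clinical CSVs can be
inspected rather than lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional

__all__ = [
    "CystKind",
    "TubalLesion",
    "OvarySideFinding",
    "AdhesionMap",
    "PainMap",
    "UterineFindings",
    "RareSiteFindings",
    "Outcomes",
    "PatientExam",
    "ExamValidationError",
    "validate_exam",
    "canonical_adhesion_sites",
    "canonical_pain_regions",
    "render_finding_map",
    "worked_example",
    "empty_exam",
    "round_half_up_1dp",
    "CROSS_SECTIONAL_SITES",
    "LONGITUDINAL_SITES",
    "ADHESION_SITES",
    "PAIN_REGION_NUMERALS",
    "PAIN_REGION_NAMES",
    "RARE_SITES",
]

# Sliding-sign sites: five on the cross-sectional sweep, five on the
# longitudinal sweep of the uterus/ovaries.
CROSS_SECTIONAL_SITES: tuple[str, ...] = (
    "Rt.O-side",
    "Rt.O-Ut.",
    "Inter O-O",
    "Lt.O-Ut.",
    "Lt.O-Side",
)
LONGITUDINAL_SITES: tuple[str, ...] = (
    "Upper ant.",
    "Mid. ant.",
    "Upper post.",
    "Mid.post.",
    "Lower post.",
)
ADHESION_SITES: tuple[str, ...] = CROSS_SECTIONAL_SITES + LONGITUDINAL_SITES

# Sites whose adhesion suggests pouch-of-Douglas involvement (posterior wall).
DOUGLAS_AREA_SITES: tuple[str, ...] = ("Upper post.", "Mid.post.", "Lower post.")

PAIN_REGION_NUMERALS: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI", "VII")
PAIN_REGION_NAMES: dict[str, str] = {
    "I": "right adnexal region",
    "II": "right uterosacral ligament area",
    "III": "anterior vaginal wall area",
    "IV": "cervical area",
    "V": "pouch of Douglas",
    "VI": "left adnexal region",
    "VII": "left uterosacral ligament area",
}

RARE_SITES: tuple[str, ...] = (
    "intestinal",
    "bladder",
    "ureteral",
    "vaginal",
    "cutaneous",
    "umbilical",
    "inguinal",
)

_MAX_DIAMETER_CM = 50.0  # sanity bound on any recorded diameter


def round_half_up_1dp(value: float) -> float:
    """Round to one decimal place with ties away from zero (clinical rounding)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class CystKind(str, Enum):
    NONE = "none"
    ENDOMETRIOMA = "endometrioma"
    OTHER = "other"


class TubalLesion(str, Enum):
    NONE = "none"
    HYDROSALPINX = "hydrosalpinx"
    PYOSALPINX = "pyosalpinx"
    OTHER = "other"


TUBAL_ABBREV: dict[TubalLesion, str] = {
    TubalLesion.HYDROSALPINX: "h.s",
    TubalLesion.PYOSALPINX: "p.s",
}


@dataclass(frozen=True)
class OvarySideFinding:
    """Cyst and tubal findings for one adnexa.

    ``cyst_diameter_cm`` is the maximum diameter on ultrasound, to one decimal
    place; for multi-cystic ovaries it is the *total* of the maximum diameters.
    Non-endometrioma cysts carry a one-letter type initial in ``cyst_label``
    (e.g. ``d`` for dermoid); tubal "other" lesions carry a short label.
    """

    side: str  # "right" | "left"
    cyst_diameter_cm: float = 0.0
    cyst_kind: CystKind = CystKind.NONE
    cyst_label: Optional[str] = None
    tubal_lesion: TubalLesion = TubalLesion.NONE
    tubal_label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cyst_diameter_cm", round_half_up_1dp(self.cyst_diameter_cm)
        )


@dataclass(frozen=True)
class AdhesionMap:
    """Sliding-sign result at the ten canonical sites (True = adhesion present)."""

    sites: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {name: bool(self.sites.get(name, False)) for name in ADHESION_SITES}
        extra = {k: v for k, v in self.sites.items() if k not in ADHESION_SITES}
        full.update(extra)  # kept so validation can name the offending key
        object.__setattr__(self, "sites", full)

    @classmethod
    def from_positives(cls, *positive: str) -> "AdhesionMap":
        return cls({name: True for name in positive})

    def positive_sites(self) -> tuple[str, ...]:
        return tuple(s for s in ADHESION_SITES if self.sites.get(s, False))


@dataclass(frozen=True)
class PainMap:
    """Palpation pain NRS (integer 0-10) for regions I-VII."""

    values: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {num: self.values.get(num, 0) for num in PAIN_REGION_NUMERALS}
        extra = {k: v for k, v in self.values.items() if k not in PAIN_REGION_NUMERALS}
        full.update(extra)
        object.__setattr__(self, "values", full)

    def max_region(self) -> tuple[str, int]:
        """(numeral, NRS) of the most painful region, first in I-VII order."""
        best = max(self.values.get(n, 0) for n in PAIN_REGION_NUMERALS)
        for numeral in PAIN_REGION_NUMERALS:
            if self.values.get(numeral, 0) == best:
                return numeral, best
        return "I", 0  # unreachable for a well-formed map


@dataclass(frozen=True)
class UterineFindings:
    """Uterine lesions: retroversion (R), adenomyosis (A), endometriotic
    nodules (E, diameters in cm, each >= 1.0) and myoma (M, noted, never scored)."""

    retroverted: bool = False
    adenomyosis: bool = False
    nodules_cm: tuple[float, ...] = ()
    myoma: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "nodules_cm", tuple(round_half_up_1dp(d) for d in self.nodules_cm)
        )


@dataclass(frozen=True)
class RareSiteFindings:
    """Rare-site endometriosis. Sites are canonical names or ``other:<label>``."""

    sites: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", frozenset(self.sites))

    def ordered(self) -> tuple[str, ...]:
        known = [s for s in RARE_SITES if s in self.sites]
        other = sorted(s for s in self.sites if s not in RARE_SITES)
        return tuple(known + other)


@dataclass(frozen=True)
class Outcomes:
    """Optional surgical outcomes: duration y (min), blood loss (mL), r-ASRM score."""

    duration_min: Optional[float] = None
    blood_loss_ml: Optional[float] = None
    rasrm_score: Optional[int] = None


@dataclass(frozen=True)
class PatientExam:
    patient_id: str
    right: OvarySideFinding = field(
        default_factory=lambda: OvarySideFinding(side="right")
    )
    left: OvarySideFinding = field(default_factory=lambda: OvarySideFinding(side="left"))
    adhesions: AdhesionMap = field(default_factory=AdhesionMap)
    pain: PainMap = field(default_factory=PainMap)
    uterus: UterineFindings = field(default_factory=UterineFindings)
    rare: RareSiteFindings = field(default_factory=RareSiteFindings)
    outcomes: Optional[Outcomes] = None


class ExamValidationError(ValueError):
    """Raised by operations that require a valid exam."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations))


def _validate_side(f: OvarySideFinding) -> list[str]:
    v: list[str] = []
    tag = f"{f.side} ovary"
    if f.side not in ("right", "left"):
        v.append(f"side: must be 'right' or 'left', got {f.side!r}")
    d = f.cyst_diameter_cm
    if d < 0:
        v.append(f"{tag}: cyst_diameter_cm must be non-negative, got {d}")
    if d >= _MAX_DIAMETER_CM:
        v.append(f"{tag}: cyst_diameter_cm must be < {_MAX_DIAMETER_CM:g} cm, got {d}")
    if f.cyst_kind == CystKind.NONE and d != 0:
        v.append(f"{tag}: cyst_diameter_cm must be 0 when cyst_kind is none")
    if f.cyst_kind != CystKind.NONE and d == 0:
        v.append(f"{tag}: cyst_diameter_cm must be > 0 when a cyst is recorded")
    if f.cyst_kind == CystKind.OTHER:
        if not (f.cyst_label and len(f.cyst_label) == 1 and f.cyst_label.islower()):
            v.append(f"{tag}: cyst_label must be a single lowercase letter for kind 'other'")
    elif f.cyst_label is not None:
        v.append(f"{tag}: cyst_label only applies to cyst_kind 'other'")
    if f.tubal_lesion == TubalLesion.OTHER:
        if not (f.tubal_label and f.tubal_label.isalpha() and f.tubal_label.islower()):
            v.append(f"{tag}: tubal_label must be non-empty lowercase letters for lesion 'other'")
    elif f.tubal_label is not None:
        v.append(f"{tag}: tubal_label only applies to tubal_lesion 'other'")
    return v


def validate_exam(exam: PatientExam) -> list[str]:
    """Check every invariant; return one message per violation (never raises)."""
    v: list[str] = []
    if not exam.patient_id:
        v.append("patient_id: must be non-empty")
    if exam.right.side != "right":
        v.append("right: side field must be 'right'")
    if exam.left.side != "left":
        v.append("left: side field must be 'left'")
    v += _validate_side(exam.right)
    v += _validate_side(exam.left)

    for name in exam.adhesions.sites:
        if name not in ADHESION_SITES:
            v.append(f"adhesions: unknown site {name!r}")
    for name, val in exam.adhesions.sites.items():
        if not isinstance(val, bool):
            v.append(f"adhesions[{name}]: must be boolean, got {val!r}")

    for numeral, nrs in exam.pain.values.items():
        if numeral not in PAIN_REGION_NUMERALS:
            v.append(f"pain: unknown region {numeral!r}")
            continue
        if not isinstance(nrs, int) or isinstance(nrs, bool):
            v.append(f"pain[{numeral}]: NRS must be an integer, got {nrs!r}")
        elif not 0 <= nrs <= 10:
            v.append(f"pain[{numeral}]: NRS must be within 0-10, got {nrs}")

    for d in exam.uterus.nodules_cm:
        if d < 1.0:
            v.append(
                f"uterus.nodules_cm: nodule diameter {d} cm below the 1 cm floor "
                "(only lesions >= 1 cm count as E)"
            )
        if d >= _MAX_DIAMETER_CM:
            v.append(f"uterus.nodules_cm: nodule diameter {d} cm fails the sanity bound")

    for site in exam.rare.sites:
        if site in RARE_SITES:
            continue
        if site.startswith("other:") and len(site) > 6 and site[6:].isalpha() and site[6:].islower():
            continue
        v.append(f"rare: unknown site {site!r} (expected canonical name or 'other:<label>')")

    if exam.outcomes is not None:
        o = exam.outcomes
        if o.duration_min is not None and o.duration_min <= 0:
            v.append(f"outcomes.duration_min: must be positive, got {o.duration_min}")
        if o.blood_loss_ml is not None and o.blood_loss_ml < 0:
            v.append(f"outcomes.blood_loss_ml: must be non-negative, got {o.blood_loss_ml}")
        if o.rasrm_score is not None and not 0 <= o.rasrm_score <= 150:
            v.append(f"outcomes.rasrm_score: must be within 0-150, got {o.rasrm_score}")
    return v


def canonical_adhesion_sites() -> list[str]:
    """The ten sliding-sign sites, cross-sectional five then longitudinal five."""
    return list(ADHESION_SITES)


def canonical_pain_regions() -> list[str]:
    """Region descriptors 'I. right adnexal region' ... 'VII. left uterosacral ligament area'."""
    return [f"{num}. {PAIN_REGION_NAMES[num]}" for num in PAIN_REGION_NUMERALS]


# ---------------------------------------------------------------------------
# Physical Finding Map rendering
# ---------------------------------------------------------------------------

_CELL = 12  # fixed cell width keeps the layout deterministic

# Pain regions arranged around the cervix (IV): anterior row on top,
# adnexa on the middle row, posterior structures (Douglas pouch V) below.
_PAIN_LAYOUT: tuple[tuple[Optional[str], ...], ...] = (
    (None, "III", None),
    ("I", "IV", "VI"),
    ("II", "V", "VII"),
)


def _cyst_cell(f: OvarySideFinding) -> str:
    parts = ""
    if f.cyst_kind == CystKind.ENDOMETRIOMA:
        parts = f"{f.cyst_diameter_cm:.1f}"
    elif f.cyst_kind == CystKind.OTHER:
        parts = f"{f.cyst_label}{f.cyst_diameter_cm:.1f}"
    if f.tubal_lesion != TubalLesion.NONE:
        abbrev = TUBAL_ABBREV.get(f.tubal_lesion, f.tubal_label or "?")
        parts = f"{parts}({abbrev})" if parts else abbrev
    return parts


def _uterine_cell(u: UterineFindings) -> str:
    codes: list[str] = []
    if u.retroverted:
        codes.append("R")
    if u.adenomyosis:
        codes.append("A")
    codes += [f"E{d:.1f}" for d in u.nodules_cm]
    if u.myoma:
        codes.append("M")
    return ",".join(codes)


def render_finding_map(exam: PatientExam) -> str:
    """Render the three 3x3 grids (adnexa | uterus | pain map) as plain text.

    Raises :class:`ExamValidationError` if the exam is invalid.
    """
    violations = validate_exam(exam)
    if violations:
        raise ExamValidationError(violations)

    adnexa = [["", "", ""], ["", "", ""], ["", "", ""]]
    adnexa[1][0] = _cyst_cell(exam.right)
    adnexa[1][2] = _cyst_cell(exam.left)

    uterus = [["", "", ""], ["", _uterine_cell(exam.uterus), ""], ["", "", ""]]

    pain = [
        ["" if num is None else str(exam.pain.values.get(num, 0)) for num in row]
        for row in _PAIN_LAYOUT
    ]

    def fmt(cell: str) -> str:
        return cell[:_CELL].center(_CELL)

    header = " | ".join(
        title.center(3 * _CELL + 2) for title in ("Adnexa (R..L)", "Uterus", "Pain NRS")
    )
    lines = [header]
    for r in range(3):
        row = " | ".join(
            "|".join(fmt(grid[r][c]) for c in range(3)) for grid in (adnexa, uterus, pain)
        )
        lines.append(row)
    return "\n".join(lines)


def worked_example(patient_id: str = "example") -> PatientExam:
    """The fully-worked demonstration exam used across the docs and tests.

    Right endometrioma 6.5 cm, left endometrioma 2.4 cm, seven adherent sites
    (four cross-sectional, three posterior longitudinal), peak palpation pain
    NRS 8 in the pouch of Douglas, adenomyosis plus a single 2.6 cm
    endometriotic nodule, no rare-site disease.  Its flat-scheme E-score is 29
    (cyst 8 + adhesion 7 + pain 8 + uterine 6 + rare 0).
    """
    return PatientExam(
        patient_id=patient_id,
        right=OvarySideFinding(
            side="right", cyst_diameter_cm=6.5, cyst_kind=CystKind.ENDOMETRIOMA
        ),
        left=OvarySideFinding(
            side="left", cyst_diameter_cm=2.4, cyst_kind=CystKind.ENDOMETRIOMA
        ),
        adhesions=AdhesionMap.from_positives(
            "Rt.O-side",
            "Rt.O-Ut.",
            "Inter O-O",
            "Lt.O-Ut.",
            "Upper post.",
            "Mid.post.",
            "Lower post.",
        ),
        pain=PainMap({"I": 4, "II": 5, "III": 2, "IV": 3, "V": 8, "VI": 4, "VII": 5}),
        uterus=UterineFindings(adenomyosis=True, nodules_cm=(2.6,)),
        rare=RareSiteFindings(),
    )


def empty_exam(patient_id: str = "empty") -> PatientExam:
    """An exam with no findings at all (every component scores 0)."""
    return PatientExam(patient_id=patient_id)
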