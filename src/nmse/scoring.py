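"""NMS-E component scores, the E-score, and variant scoring schemes.

The E-score is the sum of five components computed from the Physical Finding
Map:

* cyst score — per-side endometrioma score ``min(5, ceil(diameter))`` summed
  over both ovaries (ovarian part capped at 10), plus 3 points per side with a
  tubal lesion (hydro-/pyosalpinx etc., 0-6 extra);
* adhesion score — the number of sliding-sign-positive sites (0-10);
* pain score — the highest palpation NRS over regions I-VII (0-10);
* uterine score — 3 points per lesion *type* present among retroversion (R),
  adenomyosis (A) and endometriotic nodules (E) under the flat scheme, or a
  size-graded nodule term (3/6/10 points per nodule for diameters in
  [1,2), [2,3), [3,inf) cm, cumulatively added) under the sized scheme;
  myoma is recorded but never scored;
* rare-site score — a flat 10 points when any rare-site lesion is present.

``variant_score`` recombines any subset of the components, which is how the
partial scores of the correlation analysis (adhesion only, adhesion+pain,
cyst+adhesion+pain, ...) are expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .exam import (
    AdhesionMap,
    CystKind,
    ExamValidationError,
    OvarySideFinding,
    PainMap,
    PatientExam,
    RareSiteFindings,
    TubalLesion,
    UterineFindings,
    validate_exam,
)

__all__ = [
    "ENoduleScheme",
    "ScoreBreakdown",
    "VariantSpec",
    "cyst_side_score",
    "tubal_score",
    "combined_cyst_score",
    "adhesion_score",
    "pain_score",
    "uterine_score",
    "nodule_points",
    "rare_score",
    "e_score",
    "variant_score",
    "standard_variants",
]

_SIDE_CAP = 5  # one endometrioma scores at most 5 points
_OVARIAN_CAP = 10  # combined ovarian part (redundant with 2 x side cap; asserted)
_TUBAL_POINTS = 3
_RARE_POINTS = 10
_LESION_POINTS = 3  # per uterine lesion type under the flat scheme


class ENoduleScheme(str, Enum):
    """How endometriotic nodules (E) contribute to the uterine score.

    ``FLAT3``: 3 points once if any nodule is present, regardless of number,
    keeping the uterine score within 0-9.  ``SIZED``: 3/6/10 points per nodule
    for diameters in [1,2), [2,3), [3,inf) cm, cumulatively added (the score
    is then unbounded above).
    """

    FLAT3 = "flat3"
    SIZED = "sized_3_6_10"


@dataclass(frozen=True)
class ScoreBreakdown:
    """All component scores plus the total E-score (symbol x of the duration model)."""

    cyst_right: int
    cyst_left: int
    tubal: int
    adhesion_score: int
    pain_score: int
    uterine_score: int
    rare_score: int
    scheme: ENoduleScheme = ENoduleScheme.FLAT3

    @property
    def cyst_score(self) -> int:
        """Combined cyst score: both ovaries plus the tubal term."""
        return self.cyst_right + self.cyst_left + self.tubal

    @property
    def e_score(self) -> int:
        return (
            self.cyst_score
            + self.adhesion_score
            + self.pain_score
            + self.uterine_score
            + self.rare_score
        )


def _ceil_1dp(diameter: float) -> int:
    # diameters are held to one decimal place; guard against float fuzz at
    # integers (3.0000000004 must not ceil to 4)
    return math.ceil(round(diameter, 6))


def cyst_side_score(finding: OvarySideFinding) -> int:
    """Per-side cyst score: endometrioma -> min(5, ceil(diameter)); else 0."""
    if finding.cyst_diameter_cm < 0:
        raise ValueError(f"negative cyst diameter: {finding.cyst_diameter_cm}")
    if finding.cyst_kind != CystKind.ENDOMETRIOMA or finding.cyst_diameter_cm == 0:
        return 0
    return min(_SIDE_CAP, _ceil_1dp(finding.cyst_diameter_cm))


def tubal_score(right: OvarySideFinding, left: OvarySideFinding) -> int:
    """3 points per side with any tubal lesion (0, 3 or 6)."""
    return sum(
        _TUBAL_POINTS for f in (right, left) if f.tubal_lesion != TubalLesion.NONE
    )


def combined_cyst_score(right: OvarySideFinding, left: OvarySideFinding) -> int:
    """Both per-side cyst scores plus the tubal term (0-16)."""
    ovarian = cyst_side_score(right) + cyst_side_score(left)
    assert ovarian <= _OVARIAN_CAP  # automatic given the per-side cap
    return ovarian + tubal_score(right, left)


def adhesion_score(adhesions: AdhesionMap) -> int:
    """Number of sliding-sign-positive sites (0-10)."""
    return len(adhesions.positive_sites())


def pain_score(pain: PainMap) -> int:
    """Maximum NRS over the seven regions (0-10)."""
    return pain.max_region()[1]


def nodule_points(diameter_cm: float, scheme: ENoduleScheme) -> int:
    """Points contributed by one endometriotic nodule of the given diameter."""
    if scheme == ENoduleScheme.FLAT3:
        return _LESION_POINTS
    if diameter_cm < 2.0:
        return 3
    if diameter_cm < 3.0:
        return 6
    return 10


def uterine_score(
    findings: UterineFindings, scheme: ENoduleScheme = ENoduleScheme.FLAT3
) -> int:
    """Uterine score: 3 per lesion type (R, A) plus the nodule term; myoma scores 0."""
    score = 0
    if findings.retroverted:
        score += _LESION_POINTS
    if findings.adenomyosis:
        score += _LESION_POINTS
    if findings.nodules_cm:
        if scheme == ENoduleScheme.FLAT3:
            # one lesion type: 3 points regardless of the number of nodules
            score += _LESION_POINTS
        else:
            score += sum(nodule_points(d, scheme) for d in findings.nodules_cm)
    return score


def rare_score(findings: RareSiteFindings) -> int:
    """A flat 10 points when any rare-site lesion is present, else 0."""
    return _RARE_POINTS if findings.sites else 0


def e_score(
    exam: PatientExam, scheme: ENoduleScheme = ENoduleScheme.FLAT3
) -> ScoreBreakdown:
    """Full component breakdown and E-score total for a valid exam."""
    violations = validate_exam(exam)
    if violations:
        raise ExamValidationError(violations)
    return ScoreBreakdown(
        cyst_right=cyst_side_score(exam.right),
        cyst_left=cyst_side_score(exam.left),
        tubal=tubal_score(exam.right, exam.left),
        adhesion_score=adhesion_score(exam.adhesions),
        pain_score=pain_score(exam.pain),
        uterine_score=uterine_score(exam.uterus, scheme),
        rare_score=rare_score(exam.rare),
        scheme=scheme,
    )


@dataclass(frozen=True)
class VariantSpec:
    """Which components (and which nodule scheme) a score variant includes.

    ``uterine_elements`` restricts the uterine term to a subset of
    {"A", "R", "E"}; it must be empty when ``include_uterine`` is False.
    """

    include_cyst: bool = False
    include_adhesion: bool = False
    include_pain: bool = False
    include_uterine: bool = False
    uterine_elements: frozenset[str] = frozenset()
    e_scheme: ENoduleScheme = ENoduleScheme.FLAT3
    include_rare: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "uterine_elements", frozenset(self.uterine_elements))
        unknown = self.uterine_elements - {"A", "R", "E"}
        if unknown:
            raise ValueError(f"unknown uterine elements: {sorted(unknown)}")
        if not self.include_uterine and self.uterine_elements:
            raise ValueError("uterine_elements must be empty when include_uterine is False")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        parts = []
        if self.include_cyst:
            parts.append("CS")
        if self.include_adhesion:
            parts.append("AS")
        if self.include_pain:
            parts.append("PS")
        if self.include_uterine:
            elems = ",".join(sorted(self.uterine_elements))
            tag = "sized" if self.e_scheme == ENoduleScheme.SIZED else "flat"
            parts.append(f"US({elems};{tag})")
        if self.include_rare:
            parts.append("RS")
        return "+".join(parts) if parts else "none"

    @classmethod
    def full(
        cls, scheme: ENoduleScheme = ENoduleScheme.FLAT3, name: str | None = None
    ) -> "VariantSpec":
        """The complete E-score: CS + AS + PS + US(A,R,E) + RS."""
        return cls(
            include_cyst=True,
            include_adhesion=True,
            include_pain=True,
            include_uterine=True,
            uterine_elements=frozenset({"A", "R", "E"}),
            e_scheme=scheme,
            include_rare=True,
            name=name or ("E-score" if scheme == ENoduleScheme.FLAT3 else "E-score (sized E)"),
        )

    @classmethod
    def single(cls, component: str) -> "VariantSpec":
        """One-component variants: 'cyst', 'adhesion', 'pain' or 'uterine'."""
        if component == "cyst":
            return cls(include_cyst=True, name="Cyst score")
        if component == "adhesion":
            return cls(include_adhesion=True, name="Adhesion score")
        if component == "pain":
            return cls(include_pain=True, name="Pain score")
        if component == "uterine":
            return cls(
                include_uterine=True,
                uterine_elements=frozenset({"A", "R", "E"}),
                name="Uterine score",
            )
        raise ValueError(f"unknown component {component!r}")


def _restricted_uterine(
    findings: UterineFindings, elements: frozenset[str], scheme: ENoduleScheme
) -> int:
    score = 0
    if "R" in elements and findings.retroverted:
        score += _LESION_POINTS
    if "A" in elements and findings.adenomyosis:
        score += _LESION_POINTS
    if "E" in elements and findings.nodules_cm:
        if scheme == ENoduleScheme.FLAT3:
            score += _LESION_POINTS
        else:
            score += sum(nodule_points(d, scheme) for d in findings.nodules_cm)
    return score


def variant_score(exam: PatientExam, spec: VariantSpec) -> int:
    """Sum of only the components the variant includes."""
    total = 0
    if spec.include_cyst:
        total += combined_cyst_score(exam.right, exam.left)
    if spec.include_adhesion:
        total += adhesion_score(exam.adhesions)
    if spec.include_pain:
        total += pain_score(exam.pain)
    if spec.include_uterine:
        total += _restricted_uterine(exam.uterus, spec.uterine_elements, spec.e_scheme)
    if spec.include_rare:
        total += rare_score(exam.rare)
    return total


def standard_variants(scheme: ENoduleScheme = ENoduleScheme.FLAT3) -> list[VariantSpec]:
    """The score columns of the cohort correlation table: each single
    component plus the full E-score."""
    return [
        VariantSpec.single("cyst"),
        VariantSpec.single("adhesion"),
        VariantSpec.single("pain"),
        VariantSpec.single("uterine"),
        VariantSpec.full(scheme),
    ]
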