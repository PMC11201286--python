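"""The one-line NMS-E summary notation (serialize + parse).

The summary condenses a Physical Finding Map into a single shareable line,
in the spirit of the TNM notation::

    Cy R6.5/L2.4 | Ad7/10 | P8@V | Ut A,E2.6 | Rare - | E=29

Grammar (version ``nmse-summary/1``; a line may be prefixed with
``nmse-summary/1: ``, and any other version is rejected):

* ``Cy R<side>/L<side>`` — per adnexa: an endometrioma size in cm (one
  decimal), a non-endometrioma size with its one-letter type initial
  (``d4.0``), or ``-``; a tubal lesion abbreviation in parentheses
  (``(h.s)`` hydrosalpinx, ``(p.s)`` pyosalpinx, anything else a free label).
* ``Ad<k>/10`` — number of sliding-sign-positive adhesion sites.
* ``P<max>@<region>`` — highest palpation NRS and the (first) region I-VII
  attaining it; ``P0@-`` when no pain at all.
* ``Ut <elements>`` — comma list of R, A, E<size>, M in that order, or ``-``.
* ``Rare <sites>`` — comma list of rare-site names, or ``-``.
* ``E=<total>`` — the flat-scheme E-score; the parser recomputes it from the
  other fields and rejects lines where the two disagree.

A summary is lossy by design: it carries the adhesion *count* but not which
sites, and the peak pain but not the full map.  :func:`parse_summary` therefore
returns a :class:`ParsedSummary` of summary-level aggregates with
``complete=False`` rather than a full exam.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .exam import (
    CystKind,
    ExamValidationError,
    OvarySideFinding,
    PatientExam,
    RareSiteFindings,
    TUBAL_ABBREV,
    TubalLesion,
    UterineFindings,
    validate_exam,
)
from .scoring import (
    ENoduleScheme,
    adhesion_score as _adhesion_score,
    cyst_side_score,
    e_score,
    rare_score as _rare_score,
    tubal_score,
    uterine_score,
)

__all__ = [
    "GRAMMAR_VERSION",
    "ParsedSummary",
    "SummaryParseError",
    "SummaryConsistencyError",
    "serialize_summary",
    "parse_summary",
]

GRAMMAR_VERSION = "nmse-summary/1"


class SummaryParseError(ValueError):
    """Malformed summary text; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class SummaryConsistencyError(ValueError):
    """The embedded E= total disagrees with the score recomputed from the line."""


@dataclass(frozen=True)
class ParsedSummary:
    """Summary-level aggregates recovered from one line.

    ``complete`` is always False: a summary cannot say *which* adhesion sites
    are positive nor the full pain map, only the count and the peak.
    """

    right: OvarySideFinding
    left: OvarySideFinding
    adhesion_count: int
    pain_max: int
    pain_region: Optional[str]  # numeral I-VII, None when pain_max == 0
    uterus: UterineFindings
    rare: RareSiteFindings
    e_total: int
    complete: bool = False

    def recomputed_e_total(self) -> int:
        """Flat-scheme E-score implied by the aggregates."""
        return (
            cyst_side_score(self.right)
            + cyst_side_score(self.left)
            + tubal_score(self.right, self.left)
            + self.adhesion_count
            + self.pain_max
            + uterine_score(self.uterus, ENoduleScheme.FLAT3)
            + _rare_score(self.rare)
        )


def _side_part(f: OvarySideFinding) -> str:
    if f.cyst_kind == CystKind.ENDOMETRIOMA:
        body = f"{f.cyst_diameter_cm:.1f}"
    elif f.cyst_kind == CystKind.OTHER:
        body = f"{f.cyst_label}{f.cyst_diameter_cm:.1f}"
    else:
        body = "-"
    if f.tubal_lesion != TubalLesion.NONE:
        abbrev = TUBAL_ABBREV.get(f.tubal_lesion, f.tubal_label or "")
        body += f"({abbrev})"
    return body


def _ut_part(u: UterineFindings) -> str:
    codes: list[str] = []
    if u.retroverted:
        codes.append("R")
    if u.adenomyosis:
        codes.append("A")
    codes += [f"E{d:.1f}" for d in u.nodules_cm]
    if u.myoma:
        codes.append("M")
    return ",".join(codes) if codes else "-"


def serialize_summary(exam: PatientExam) -> str:
    """Canonical one-line summary of a valid exam (deterministic)."""
    violations = validate_exam(exam)
    if violations:
        raise ExamValidationError(violations)
    breakdown = e_score(exam, ENoduleScheme.FLAT3)
    region, peak = exam.pain.max_region()
    pain_part = f"P{peak}@{region if peak > 0 else '-'}"
    rare_part = ",".join(exam.rare.ordered()) if exam.rare.sites else "-"
    return (
        f"Cy R{_side_part(exam.right)}/L{_side_part(exam.left)}"
        f" | Ad{breakdown.adhesion_score}/10"
        f" | {pain_part}"
        f" | Ut {_ut_part(exam.uterus)}"
        f" | Rare {rare_part}"
        f" | E={breakdown.e_score}"
    )


_SIDE_RE = re.compile(
    r"^(?:(?P<none>-)|(?P<prefix>[a-z])?(?P<size>\d{1,2}\.\d))"
    r"(?:\((?P<tube>[a-z.]+)\))?$"
)


def _parse_side(text: str, side: str, pos: int) -> OvarySideFinding:
    m = _SIDE_RE.match(text)
    if not m:
        raise SummaryParseError(f"cannot parse {side} adnexa {text!r}", pos)
    if m.group("none"):
        kind, label, diameter = CystKind.NONE, None, 0.0
    elif m.group("prefix"):
        kind, label, diameter = CystKind.OTHER, m.group("prefix"), float(m.group("size"))
    else:
        kind, label, diameter = CystKind.ENDOMETRIOMA, None, float(m.group("size"))
    tube = m.group("tube")
    if tube is None:
        lesion, tlabel = TubalLesion.NONE, None
    elif tube == "h.s":
        lesion, tlabel = TubalLesion.HYDROSALPINX, None
    elif tube == "p.s":
        lesion, tlabel = TubalLesion.PYOSALPINX, None
    else:
        lesion, tlabel = TubalLesion.OTHER, tube
    return OvarySideFinding(
        side=side,
        cyst_diameter_cm=diameter,
        cyst_kind=kind,
        cyst_label=label,
        tubal_lesion=lesion,
        tubal_label=tlabel,
    )


def parse_summary(text: str) -> ParsedSummary:
    """Parse one summary line back into summary-level aggregates.

    Raises :class:`SummaryParseError` on malformed text (with the character
    position) and :class:`SummaryConsistencyError` when the embedded ``E=``
    total does not match the score recomputed from the parsed fields.
    """
    original = text
    offset = 0
    if text.startswith("nmse-summary/"):
        version, sep, rest = text.partition(": ")
        if version != GRAMMAR_VERSION:
            raise SummaryParseError(f"unsupported grammar version {version!r}", 0)
        if not sep:
            raise SummaryParseError("version prefix must be followed by ': '", len(version))
        offset = len(version) + len(sep)
        text = rest

    segments = text.split(" | ")
    if len(segments) != 6:
        raise SummaryParseError(
            f"expected 6 ' | '-separated segments, got {len(segments)}", offset
        )
    positions = []
    pos = offset
    for seg in segments:
        positions.append(pos)
        pos += len(seg) + 3

    cy, ad, pain, ut, rare, etot = segments

    m = re.match(r"^Cy R(?P<r>[^/]+)/L(?P<l>.+)$", cy)
    if not m:
        raise SummaryParseError(f"cannot parse cyst segment {cy!r}", positions[0])
    right = _parse_side(m.group("r"), "right", positions[0])
    left = _parse_side(m.group("l"), "left", positions[0])

    m = re.match(r"^Ad(\d{1,2})/10$", ad)
    if not m:
        raise SummaryParseError(f"cannot parse adhesion segment {ad!r}", positions[1])
    adhesion_count = int(m.group(1))
    if adhesion_count > 10:
        raise SummaryParseError(
            f"adhesion count {adhesion_count} exceeds the 10 sites", positions[1]
        )

    m = re.match(r"^P(\d{1,2})@(I{1,3}|IV|VI{0,2}|-)$", pain)
    if not m:
        raise SummaryParseError(f"cannot parse pain segment {pain!r}", positions[2])
    pain_max = int(m.group(1))
    pain_region = None if m.group(2) == "-" else m.group(2)
    if pain_max > 10:
        raise SummaryParseError(f"pain NRS {pain_max} exceeds 10", positions[2])
    if (pain_max == 0) != (pain_region is None):
        raise SummaryParseError(
            "pain region must be '-' exactly when the peak NRS is 0", positions[2]
        )

    if not ut.startswith("Ut "):
        raise SummaryParseError(f"cannot parse uterine segment {ut!r}", positions[3])
    ut_body = ut[3:]
    retro = adeno = myoma = False
    nodules: list[float] = []
    if ut_body != "-":
        for code in ut_body.split(","):
            if code == "R":
                retro = True
            elif code == "A":
                adeno = True
            elif code == "M":
                myoma = True
            elif re.match(r"^E\d{1,2}\.\d$", code):
                nodules.append(float(code[1:]))
            else:
                raise SummaryParseError(
                    f"unknown uterine element {code!r}", positions[3]
                )
    uterus = UterineFindings(
        retroverted=retro, adenomyosis=adeno, nodules_cm=tuple(nodules), myoma=myoma
    )

    if not rare.startswith("Rare "):
        raise SummaryParseError(f"cannot parse rare segment {rare!r}", positions[4])
    rare_body = rare[5:]
    sites: frozenset[str] = frozenset()
    if rare_body != "-":
        sites = frozenset(rare_body.split(","))
    rare_findings = RareSiteFindings(sites)

    m = re.match(r"^E=(\d+)$", etot)
    if not m:
        raise SummaryParseError(f"cannot parse total segment {etot!r}", positions[5])
    e_total = int(m.group(1))

    parsed = ParsedSummary(
        right=right,
        left=left,
        adhesion_count=adhesion_count,
        pain_max=pain_max,
        pain_region=pain_region,
        uterus=uterus,
        rare=rare_findings,
        e_total=e_total,
    )
    recomputed = parsed.recomputed_e_total()
    if recomputed != e_total:
        raise SummaryConsistencyError(
            f"embedded E={e_total} disagrees with recomputed flat-scheme "
            f"E-score {recomputed} for {original!r}"
        )
    return parsed
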