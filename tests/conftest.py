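"""Shared fixtures and hypothesis strategies for the nmse test suite."""

from __future__ import annotations

import hypothesis.strategies as st
import pytest
from hypothesis import HealthCheck, settings

from nmse.exam import (
    ADHESION_SITES,
    AdhesionMap,
    CystKind,
    Outcomes,
    OvarySideFinding,
    PAIN_REGION_NUMERALS,
    PainMap,
    PatientExam,
    RARE_SITES,
    RareSiteFindings,
    TubalLesion,
    UterineFindings,
    empty_exam,
    worked_example,
)
from nmse.simulate import default_cohort_spec, generate_cohort

settings.register_profile(
    "nmse",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("nmse")


@pytest.fixture
def fig_exam() -> PatientExam:
    """The fully-worked demonstration exam (flat-scheme E-score 29)."""
    return worked_example()


@pytest.fixture
def blank_exam() -> PatientExam:
    return empty_exam()


@pytest.fixture(scope="session")
def default_cohort_5000():
    """Default synthetic cohort at n=5000 with the packaged seed (shared,
    generated once per session)."""
    spec = default_cohort_spec(n=5000)
    return spec, generate_cohort(spec)


# ---------------------------------------------------------------------------
# Strategies for random *valid* exams
# ---------------------------------------------------------------------------


@st.composite
def side_findings(draw, side: str) -> OvarySideFinding:
    kind = draw(
        st.sampled_from([CystKind.NONE, CystKind.ENDOMETRIOMA, CystKind.OTHER])
    )
    if kind == CystKind.NONE:
        diameter, label = 0.0, None
    else:
        diameter = draw(st.integers(1, 499)) / 10.0
        label = draw(st.sampled_from("dmsf")) if kind == CystKind.OTHER else None
    tubal = draw(
        st.sampled_from(
            [
                TubalLesion.NONE,
                TubalLesion.HYDROSALPINX,
                TubalLesion.PYOSALPINX,
                TubalLesion.OTHER,
            ]
        )
    )
    tlabel = draw(st.sampled_from(["sactx", "occl"])) if tubal == TubalLesion.OTHER else None
    return OvarySideFinding(
        side=side,
        cyst_diameter_cm=diameter,
        cyst_kind=kind,
        cyst_label=label,
        tubal_lesion=tubal,
        tubal_label=tlabel,
    )


@st.composite
def valid_exams(draw) -> PatientExam:
    adhesions = AdhesionMap(
        {site: draw(st.booleans()) for site in ADHESION_SITES}
    )
    pain = PainMap({n: draw(st.integers(0, 10)) for n in PAIN_REGION_NUMERALS})
    nodules = tuple(
        d / 10.0 for d in draw(st.lists(st.integers(10, 120), max_size=3))
    )
    uterus = UterineFindings(
        retroverted=draw(st.booleans()),
        adenomyosis=draw(st.booleans()),
        nodules_cm=nodules,
        myoma=draw(st.booleans()),
    )
    rare_pool = list(RARE_SITES) + ["other:pleural"]
    rare = RareSiteFindings(
        frozenset(draw(st.lists(st.sampled_from(rare_pool), max_size=2, unique=True)))
    )
    outcomes = None
    if draw(st.booleans()):
        outcomes = Outcomes(
            duration_min=draw(st.integers(51, 421)) * 1.0,
            blood_loss_ml=draw(st.integers(0, 500)) * 1.0,
            rasrm_score=draw(st.integers(0, 150)),
        )
    return PatientExam(
        patient_id=draw(st.uuids().map(lambda u: f"P{u.hex[:8]}")),
        right=draw(side_findings("right")),
        left=draw(side_findings("left")),
        adhesions=adhesions,
        pain=pain,
        uterus=uterus,
        rare=rare,
        outcomes=outcomes,
    )
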