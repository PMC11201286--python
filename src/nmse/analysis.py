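"""Cohort-level statistics: rank correlations, duration regression, r-ASRM.

Spearman's rank correlation is computed as the Pearson correlation of rank
vectors, with two tie dialects:

* ``average`` — tied values receive the mean of their rank positions (the
  statistically standard definition; matches ``scipy.stats.spearmanr``);
* ``rank_eq`` — tied values all receive the minimum (first) rank, reproducing
  a spreadsheet computed with RANK.EQ feeding CORREL.  (Spreadsheet ranking
  defaults to descending order; Spearman is invariant to reversing both rank
  vectors, so ascending minimum-rank is the same statistic.)

The surgical-duration predictor is an ordinary least-squares line
``y = slope * x + intercept`` mapping the E-score x to minutes y; the
canonical fitted model is ``y = 6.2995 x + 49.459``.

The r-ASRM comparison implements the intraoperative point allocation
(peritoneal 6, endometriomas 40, cul-de-sac obliteration 40, ovarian
adhesions 32 via the {0, 4, 8, 16} category map per ovary, tubal adhesions
32; total capped at 150) and the stage bins I 1-5, II 6-15, III 16-40,
IV >= 41.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort
from .scoring import ENoduleScheme, VariantSpec, e_score, standard_variants, variant_score

__all__ = [
    "TieMode",
    "CorrelationResult",
    "CorrelationTable",
    "DurationModel",
    "CANONICAL_DURATION_MODEL",
    "RASRMFindings",
    "OVARIAN_ADHESION_POINTS",
    "rank_vector",
    "spearman",
    "correlation_table",
    "fit_duration_model",
    "predict_duration",
    "rasrm_total",
    "rasrm_stage",
    "cohort_descriptives",
]


class TieMode(str, Enum):
    AVERAGE = "average"
    RANK_EQ = "rank_eq"


_RANKDATA_METHOD = {TieMode.AVERAGE: "average", TieMode.RANK_EQ: "min"}


def rank_vector(values: Sequence[float], mode: TieMode = TieMode.AVERAGE) -> np.ndarray:
    """Ascending ranks 1..n with the chosen tie dialect."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    return stats.rankdata(arr, method=_RANKDATA_METHOD[TieMode(mode)])


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    n: int
    tie_mode: TieMode
    p_value: float


def spearman(
    x: Sequence[float], y: Sequence[float], mode: TieMode = TieMode.AVERAGE
) -> CorrelationResult:
    """Spearman rho as the Pearson correlation of rank vectors.

    The p-value is the large-sample two-sided t approximation with n-2
    degrees of freedom.  Constant input vectors make the correlation
    undefined and raise ValueError.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = rank_vector(xa, mode)
    ry = rank_vector(ya, mode)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(coefficient=rho, n=n, tie_mode=TieMode(mode), p_value=p)


@dataclass
class CorrelationTable:
    """Spearman coefficients of each score variant (rows) against each outcome."""

    results: pd.DataFrame  # cells are CorrelationResult

    @property
    def coefficients(self) -> pd.DataFrame:
        return self.results.map(lambda r: r.coefficient if r is not None else float("nan"))

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        """Presentation form: coefficients rounded like the printed tables."""
        return self.coefficients.round(decimals)


def correlation_table(
    cohort: Cohort,
    variants: Optional[Sequence[VariantSpec]] = None,
    outcomes: Sequence[str] = ("rasrm_score", "duration_min", "blood_loss_ml"),
    mode: TieMode = TieMode.AVERAGE,
    include_rasrm_row: bool = True,
) -> CorrelationTable:
    """Correlate every variant score (and the r-ASRM score) with each outcome.

    Pairs with a missing outcome value are dropped cell-wise; a cell with
    fewer than 3 complete pairs, or an outcome absent from every patient,
    raises ValueError naming the outcome.
    """
    if variants is None:
        variants = standard_variants()
    rows: dict[str, list[Optional[float]]] = {
        spec.label: [float(variant_score(e, spec)) for e in cohort.exams]
        for spec in variants
    }
    if include_rasrm_row:
        rows["r-ASRM score"] = [
            float(v) if v is not None else None
            for v in cohort.outcome_values("rasrm_score")
        ]
    out_cols = {name: cohort.outcome_values(name) for name in outcomes}

    table: dict[str, dict[str, CorrelationResult]] = {}
    for row_label, xs in rows.items():
        table[row_label] = {}
        for out_name, ys in out_cols.items():
            pairs = [
                (xv, yv) for xv, yv in zip(xs, ys) if xv is not None and yv is not None
            ]
            if len(pairs) < 3:
                raise ValueError(
                    f"outcome {out_name!r}: fewer than 3 complete pairs for "
                    f"{row_label!r}"
                )
            xv, yv = zip(*pairs)
            table[row_label][out_name] = spearman(xv, yv, mode)
    frame = pd.DataFrame(
        {out: {row: table[row][out] for row in table} for out in out_cols}
    ).reindex(index=list(rows), columns=list(outcomes))
    return CorrelationTable(results=frame)


@dataclass(frozen=True)
class DurationModel:
    """Affine surgical-duration predictor: minutes = slope * E-score + intercept."""

    slope: float
    intercept: float

    def predict(self, e_score_value: float) -> float:
        if e_score_value < 0:
            raise ValueError(f"E-score must be non-negative, got {e_score_value}")
        return self.slope * e_score_value + self.intercept

    @classmethod
    def fit(
        cls, e_scores: Sequence[float], durations: Sequence[float]
    ) -> "DurationModel":
        """Ordinary least squares over (E-score, duration) pairs."""
        x = np.asarray(e_scores, dtype=float)
        y = np.asarray(durations, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("e_scores and durations must be equal-length 1-d vectors")
        if x.size < 2:
            raise ValueError(f"need at least 2 points, got {x.size}")
        if np.all(x == x[0]):
            raise ValueError("degenerate design: all E-scores equal")
        design = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
        return cls(slope=float(slope), intercept=float(intercept))


CANONICAL_DURATION_MODEL = DurationModel(slope=6.2995, intercept=49.459)


def fit_duration_model(
    e_scores: Sequence[float], durations: Sequence[float]
) -> DurationModel:
    return DurationModel.fit(e_scores, durations)


def predict_duration(model: DurationModel, e_score_value: float) -> float:
    return model.predict(e_score_value)


class OvarianAdhesionCategory(str, Enum):
    NONE = "none"
    LT_THIRD = "lt_third"
    THIRD_TO_TWO_THIRDS = "third_to_two_thirds"
    GT_TWO_THIRDS = "gt_two_thirds"


OVARIAN_ADHESION_POINTS: dict[OvarianAdhesionCategory, int] = {
    OvarianAdhesionCategory.NONE: 0,
    OvarianAdhesionCategory.LT_THIRD: 4,
    OvarianAdhesionCategory.THIRD_TO_TWO_THIRDS: 8,
    OvarianAdhesionCategory.GT_TWO_THIRDS: 16,
}


@dataclass(frozen=True)
class RASRMFindings:
    """Component points of the intraoperative r-ASRM worksheet (coarse level)."""

    peritoneal_points: int = 0
    endometrioma_points: int = 0
    culdesac_points: int = 0
    right_ovarian_adhesion: OvarianAdhesionCategory = OvarianAdhesionCategory.NONE
    left_ovarian_adhesion: OvarianAdhesionCategory = OvarianAdhesionCategory.NONE
    tubal_adhesion_points: int = 0


def rasrm_total(findings: RASRMFindings) -> int:
    """Total r-ASRM score, component caps enforced, overall cap 150."""
    caps = {
        "peritoneal_points": 6,
        "endometrioma_points": 40,
        "culdesac_points": 40,
        "tubal_adhesion_points": 32,
    }
    for name, cap in caps.items():
        value = getattr(findings, name)
        if not 0 <= value <= cap:
            raise ValueError(f"{name} must be within 0-{cap}, got {value}")
    total = (
        findings.peritoneal_points
        + findings.endometrioma_points
        + findings.culdesac_points
        + OVARIAN_ADHESION_POINTS[OvarianAdhesionCategory(findings.right_ovarian_adhesion)]
        + OVARIAN_ADHESION_POINTS[OvarianAdhesionCategory(findings.left_ovarian_adhesion)]
        + findings.tubal_adhesion_points
    )
    return min(total, 150)


def rasrm_stage(score: int) -> str:
    """Stage bins: I 1-5, II 6-15, III 16-40, IV 41-150."""
    if not 1 <= score <= 150:
        raise ValueError(f"r-ASRM score must be within 1-150, got {score}")
    if score <= 5:
        return "I"
    if score <= 15:
        return "II"
    if score <= 40:
        return "III"
    return "IV"


def cohort_descriptives(
    cohort: Cohort, scheme: ENoduleScheme = ENoduleScheme.FLAT3
) -> dict[str, pd.DataFrame]:
    """Cohort summary tables: score/outcome means with ranges, and lesion
    prevalences as n (%).

    Means are rounded to 2 decimals at presentation (the internal score
    columns keep full precision).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    records = []
    for exam in cohort.exams:
        b = e_score(exam, scheme)
        o = exam.outcomes
        records.append(
            {
                "Cyst score": b.cyst_score,
                "Adhesion score": b.adhesion_score,
                "Pain score": b.pain_score,
                "Uterine score": b.uterine_score,
                "E-score": b.e_score,
                "duration_min": o.duration_min if o else None,
                "blood_loss_ml": o.blood_loss_ml if o else None,
                "rasrm_score": o.rasrm_score if o else None,
            }
        )
    frame = pd.DataFrame.from_records(records).astype(float)
    scores = pd.DataFrame(
        {
            "mean": frame.mean().round(2),
            "min": frame.min(),
            "max": frame.max(),
        }
    )

    n = len(cohort)
    counts = {
        "Endometriotic nodule: E": sum(bool(e.uterus.nodules_cm) for e in cohort),
        "Retroverted uterus: R": sum(e.uterus.retroverted for e in cohort),
        "Adenomyosis: A": sum(e.uterus.adenomyosis for e in cohort),
        "Myoma: M": sum(e.uterus.myoma for e in cohort),
        "Rare-site endometriosis": sum(bool(e.rare.sites) for e in cohort),
    }
    prevalence = pd.DataFrame(
        {
            "n": pd.Series(counts),
            "%": pd.Series({k: round(100.0 * v / n, 1) for k, v in counts.items()}),
        }
    )
    return {"scores": scores, "prevalence": prevalence}
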