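"""Rank statistics, duration model, r-ASRM scoring/staging, descriptives.

The Spearman implementation is checked against two independent oracles: an
explicit rank-then-Pearson computation (tie-averaged ranks built by sorting,
Pearson from the sum formula) and, for the rank_eq dialect, spreadsheet
RANK.EQ semantics expressed as ``rank(x) = 1 + #{v < x}``.
"""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
import hypothesis.strategies as st
from scipy import stats as sps

from nmse.analysis import (
    CANONICAL_DURATION_MODEL,
    DurationModel,
    OvarianAdhesionCategory,
    RASRMFindings,
    TieMode,
    cohort_descriptives,
    correlation_table,
    rank_vector,
    rasrm_stage,
    rasrm_total,
    spearman,
)
from nmse.cohort_io import Cohort
from nmse.exam import Outcomes, worked_example
from nmse.scoring import VariantSpec, e_score
from nmse.simulate import default_cohort_spec, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_average_ranks(values):
    """Tie-averaged ascending ranks, built from an explicit sort."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # mean of 1-based positions i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_rank_eq(values):
    """Spreadsheet RANK.EQ (ascending): ties share the first/minimum rank."""
    return [1 + sum(1 for v in values if v < x) for x in values]


def oracle_pearson(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


class TestRankVector:
    def test_average_ties(self):
        assert list(rank_vector([10, 20, 20, 30], TieMode.AVERAGE)) == [1, 2.5, 2.5, 4]

    def test_rank_eq_ties_share_minimum(self):
        assert list(rank_vector([10, 20, 20, 30], TieMode.RANK_EQ)) == [1, 2, 2, 4]

    def test_singleton(self):
        for mode in TieMode:
            assert list(rank_vector([5], mode)) == [1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_vector([], TieMode.AVERAGE)

    @pytest.mark.parametrize(
        "values",
        [
            [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5],
            [-2.5, 0.0, 0.0, 7.25, -2.5, 3.0],
            [1, 1, 1, 2],
            [10.0, 9.5, 9.5, 9.5, 1.0],
        ],
    )
    def test_rank_eq_matches_spreadsheet_oracle(self, values):
        assert list(rank_vector(values, TieMode.RANK_EQ)) == oracle_rank_eq(values)

    def test_average_matches_sort_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            vals = list(rng.integers(0, 8, size=rng.integers(2, 30)).astype(float))
            assert list(rank_vector(vals, TieMode.AVERAGE)) == oracle_average_ranks(vals)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).coefficient == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).coefficient == pytest.approx(-1.0)

    def test_tied_example_matches_oracle(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        expected = oracle_pearson(oracle_average_ranks(x), oracle_average_ranks(y))
        assert spearman(x, y, TieMode.AVERAGE).coefficient == pytest.approx(
            expected, abs=1e-12
        )

    def test_average_mode_agrees_with_scipy(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x = rng.integers(0, 10, size=n).astype(float)
            y = rng.integers(0, 10, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            ours = spearman(x, y, TieMode.AVERAGE)
            ref_rho, ref_p = sps.spearmanr(x, y)
            assert ours.coefficient == pytest.approx(ref_rho, abs=1e-12)
            assert ours.p_value == pytest.approx(ref_p, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)), min_size=4, max_size=30
        ),
        mode=st.sampled_from(list(TieMode)),
    )
    def test_symmetry_and_monotone_invariance(self, data, mode):
        x = [float(a) for a, _ in data]
        y = [float(b) for _, b in data]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        rho = spearman(x, y, mode).coefficient
        assert spearman(y, x, mode).coefficient == pytest.approx(rho, abs=1e-12)
        # strictly increasing transforms leave ranks, hence rho, unchanged
        assert spearman([math.exp(v / 10) for v in x], [3 * v + 1 for v in y], mode
                        ).coefficient == pytest.approx(rho, abs=1e-12)


class TestDurationModel:
    def test_recovers_canonical_line_exactly(self):
        xs = [0.0, 5.0, 10.0, 19.0, 29.0, 36.0]
        ys = [CANONICAL_DURATION_MODEL.predict(x) for x in xs]
        fit = DurationModel.fit(xs, ys)
        assert fit.slope == pytest.approx(6.2995, abs=1e-9)
        assert fit.intercept == pytest.approx(49.459, abs=1e-9)

    def test_two_points(self):
        fit = DurationModel.fit([0, 1], [1, 2])
        assert (fit.slope, fit.intercept) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_degenerate_design(self):
        with pytest.raises(ValueError, match="degenerate"):
            DurationModel.fit([2, 2, 2], [1, 2, 3])

    @pytest.mark.parametrize(
        "x, expected", [(0, 49.459), (19, 169.1495), (29, 232.1445)]
    )
    def test_canonical_predictions(self, x, expected):
        assert CANONICAL_DURATION_MODEL.predict(x) == pytest.approx(expected, abs=1e-9)

    def test_negative_escore_rejected(self):
        with pytest.raises(ValueError):
            CANONICAL_DURATION_MODEL.predict(-1)

    @given(a=st.integers(0, 40), b=st.integers(0, 40))
    def test_affine_identity(self, a, b):
        m = CANONICAL_DURATION_MODEL
        assert m.predict(a) + m.predict(b) == pytest.approx(
            m.predict(a + b) + m.intercept, abs=1e-9
        )

    def test_ols_residual_orthogonality(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            x = rng.uniform(0, 40, size=n)
            y = 6.0 * x + 50 + rng.normal(0, 25, size=n)
            fit = DurationModel.fit(x, y)
            resid = y - (fit.slope * x + fit.intercept)
            assert abs(resid.sum()) < 1e-9 * max(1.0, abs(y).sum())
            assert abs((resid * x).sum()) < 1e-9 * max(1.0, abs(x * y).sum())


class TestRASRM:
    def test_all_caps_totals_150(self):
        findings = RASRMFindings(
            peritoneal_points=6,
            endometrioma_points=40,
            culdesac_points=40,
            right_ovarian_adhesion=OvarianAdhesionCategory.GT_TWO_THIRDS,
            left_ovarian_adhesion=OvarianAdhesionCategory.GT_TWO_THIRDS,
            tubal_adhesion_points=32,
        )
        assert rasrm_total(findings) == 150

    def test_single_ovary_dense_adhesion(self):
        findings = RASRMFindings(
            right_ovarian_adhesion=OvarianAdhesionCategory.GT_TWO_THIRDS
        )
        assert rasrm_total(findings) == 16

    def test_category_point_map(self):
        points = [
            rasrm_total(RASRMFindings(right_ovarian_adhesion=cat))
            for cat in OvarianAdhesionCategory
        ]
        assert points == [0, 4, 8, 16]

    def test_zero_and_overflow(self):
        assert rasrm_total(RASRMFindings()) == 0
        with pytest.raises(ValueError, match="peritoneal"):
            rasrm_total(RASRMFindings(peritoneal_points=7))

    @pytest.mark.parametrize(
        "score, stage",
        [(1, "I"), (5, "I"), (6, "II"), (10, "II"), (15, "II"), (16, "III"),
         (40, "III"), (41, "IV"), (150, "IV")],
    )
    def test_stage_bins(self, score, stage):
        assert rasrm_stage(score) == stage

    def test_stage_bins_partition_and_monotone(self):
        stages = [rasrm_stage(s) for s in range(1, 151)]
        order = {"I": 0, "II": 1, "III": 2, "IV": 3}
        assert all(order[b] >= order[a] for a, b in zip(stages, stages[1:]))
        assert {s for s in stages} == {"I", "II", "III", "IV"}

    def test_stage_domain(self):
        for bad in (0, 151, -3):
            with pytest.raises(ValueError):
                rasrm_stage(bad)


def _cohort_with_outcomes(rows):
    """rows: list of (exam, duration, blood, rasrm)."""
    exams = [
        dataclasses.replace(
            e, patient_id=f"c{i}", outcomes=Outcomes(duration_min=d, blood_loss_ml=b, rasrm_score=r)
        )
        for i, (e, d, b, r) in enumerate(rows)
    ]
    return Cohort(exams=exams)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(default_cohort_spec(n=60, seed=4))


class TestCorrelationTable:
    def test_cells_equal_direct_spearman(self, cohort):
        table = correlation_table(cohort)
        adhesion = [float(e_score(e).adhesion_score) for e in cohort]
        durations = [e.outcomes.duration_min for e in cohort]
        direct = spearman(adhesion, durations)
        cell = table.results.loc["Adhesion score", "duration_min"]
        assert cell.coefficient == pytest.approx(direct.coefficient, abs=1e-12)
        assert cell.n == len(cohort)

    def test_duplicated_outcome_yields_unity(self, cohort):
        rigged = Cohort(
            exams=[
                dataclasses.replace(
                    e,
                    outcomes=dataclasses.replace(
                        e.outcomes, duration_min=float(e_score(e).e_score)
                    ),
                )
                for e in cohort
            ]
        )
        table = correlation_table(rigged)
        assert table.rounded().loc["E-score", "duration_min"] == pytest.approx(1.0)

    def test_missing_outcome_named(self, fig_exam):
        bare = Cohort(exams=[dataclasses.replace(fig_exam, patient_id=f"x{i}") for i in range(5)])
        with pytest.raises(ValueError, match="rasrm_score"):
            correlation_table(bare)
        with pytest.raises(ValueError, match="duration_min"):
            correlation_table(bare, outcomes=("duration_min",), include_rasrm_row=False)

    def test_tie_modes_can_differ(self, cohort):
        avg = correlation_table(cohort, mode=TieMode.AVERAGE).coefficients
        mins = correlation_table(cohort, mode=TieMode.RANK_EQ).coefficients
        assert avg.shape == mins.shape  # both computed over the same cells
        assert (avg - mins).abs().max().max() < 0.2  # dialects agree closely


class TestDescriptives:
    def test_single_patient(self, fig_exam):
        cohort = _cohort_with_outcomes([(fig_exam, 232.0, 80.0, 74)])
        scores = cohort_descriptives(cohort)["scores"]
        row = scores.loc["E-score"]
        assert row["mean"] == row["min"] == row["max"] == 29.0

    def test_two_patient_mean_and_range(self, fig_exam, blank_exam):
        # E-scores 29 and 0 -> artificial outcomes to exercise the table
        cohort = _cohort_with_outcomes(
            [(fig_exam, 100.0, 10.0, 20), (blank_exam, 200.0, 20.0, 40)]
        )
        scores = cohort_descriptives(cohort)["scores"]
        assert scores.loc["E-score", "mean"] == pytest.approx(14.5)
        assert (scores.loc["E-score", "min"], scores.loc["E-score", "max"]) == (0.0, 29.0)

    def test_prevalence_table(self, fig_exam):
        cohort = _cohort_with_outcomes([(fig_exam, 100.0, 10.0, 20)] * 4)
        prev = cohort_descriptives(cohort)["prevalence"]
        assert prev.loc["Adenomyosis: A", "n"] == 4
        assert prev.loc["Adenomyosis: A", "%"] == 100.0
        assert prev.loc["Retroverted uterus: R", "n"] == 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_descriptives(Cohort(exams=[]))
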