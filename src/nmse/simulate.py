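"""Seeded synthetic-cohort generator (Gaussian copula over component scores).

Real NMS-E patient data are not publicly available, so scoring and analysis
are exercised against simulated cohorts whose *marginals* (component-score
distributions, lesion prevalences, outcome means and ranges) and *rank
correlation structure* are configurable and default to the published cohort
summary of the method's validation study (n=111).

The generator works at the component-score level:

1. draw a latent multivariate normal whose correlation matrix is the target
   Spearman matrix mapped through the copula identity ``r = 2 sin(pi rho / 6)``;
2. push each latent coordinate through its marginal's quantile function to get
   integer component scores (cyst, adhesion, pain, uterine);
3. *backfill* a concrete :class:`~nmse.exam.PatientExam` whose findings
   reproduce those scores exactly under the flat nodule scheme;
4. attach outcomes: duration = slope * E + intercept + Gaussian noise
   (truncated to the configured range), blood loss analogously, and an r-ASRM
   score as a monotone quantile map of a shared latent severity plus link
   noise.

Everything is deterministic given (spec, seed): the same spec produces
byte-identical cohorts.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize, special, stats

from .cohort_io import Cohort
from .exam import (
    ADHESION_SITES,
    AdhesionMap,
    CystKind,
    DOUGLAS_AREA_SITES,
    OvarySideFinding,
    Outcomes,
    PainMap,
    PAIN_REGION_NUMERALS,
    PatientExam,
    RareSiteFindings,
    TubalLesion,
    UterineFindings,
)

__all__ = [
    "COMPONENTS",
    "MarginalSpec",
    "OutcomeModel",
    "RasrmLink",
    "CohortSpec",
    "CohortSpecError",
    "latent_correlation_from_spearman",
    "uterine_score_pmf",
    "sample_component_scores",
    "backfill_exam",
    "generate_cohort",
    "default_cohort_spec",
    "load_cohort_spec",
]

COMPONENTS: tuple[str, ...] = ("cyst", "adhesion", "pain", "uterine")


class CohortSpecError(ValueError):
    """Invalid simulator configuration."""


class MarginalSpec(BaseModel):
    """One component's marginal distribution.

    ``truncated_normal``: integer scores from a normal truncated to
    [min, max]; ``mean`` is the mean of the *truncated* law (the location
    parameter is solved internally, so asymmetric truncation does not bias
    the target mean).  ``discrete_pmf``: explicit support/probabilities.
    ``bernoulli``: a prevalence (used for presence/absence draws).
    """

    kind: str
    mean: Optional[float] = None
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    values: Optional[list[float]] = None
    probs: Optional[list[float]] = None
    prevalence: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "MarginalSpec":
        if self.kind == "truncated_normal":
            if None in (self.mean, self.sd, self.min, self.max):
                raise ValueError("truncated_normal needs mean, sd, min, max")
            if not self.min < self.max:
                raise ValueError("min must be < max")
            if not self.min <= self.mean <= self.max:
                raise ValueError("mean must lie inside [min, max]")
            if self.sd <= 0:
                raise ValueError("sd must be positive")
        elif self.kind == "discrete_pmf":
            if self.values is None or self.probs is None:
                raise ValueError("discrete_pmf needs values and probs")
            if len(self.values) != len(self.probs) or not self.values:
                raise ValueError("values and probs must be equal-length, non-empty")
            if any(p < 0 for p in self.probs):
                raise ValueError("probabilities must be non-negative")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")
        elif self.kind == "bernoulli":
            if self.prevalence is None or not 0.0 <= self.prevalence <= 1.0:
                raise ValueError("bernoulli needs prevalence in [0, 1]")
        else:
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        return self

    def _truncnorm_loc(self) -> float:
        """Location parameter whose [min, max]-truncated mean equals ``mean``."""
        lo, hi, sd, target = self.min, self.max, self.sd, self.mean

        def truncated_mean(loc: float) -> float:
            a, b = (lo - loc) / sd, (hi - loc) / sd
            return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd)) - target

        span = 10.0 * sd + (hi - lo)
        return float(optimize.brentq(truncated_mean, lo - span, hi + span, xtol=1e-10))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function, returning integer scores within the support."""
        u = np.asarray(u, dtype=float)
        if self.kind == "truncated_normal":
            loc = self._truncnorm_loc()
            a, b = (self.min - loc) / self.sd, (self.max - loc) / self.sd
            x = stats.truncnorm.ppf(u, a, b, loc=loc, scale=self.sd)
            return np.clip(np.rint(x), self.min, self.max).astype(int)
        if self.kind == "discrete_pmf":
            cum = np.cumsum(self.probs)
            idx = np.minimum(np.searchsorted(cum, u, side="left"), len(self.probs) - 1)
            return np.asarray(self.values)[idx].astype(int)
        raise CohortSpecError(f"ppf not defined for kind {self.kind!r}")


class OutcomeModel(BaseModel):
    """Affine map of the E-score plus Gaussian noise, truncated to [min, max]."""

    slope: float
    intercept: float
    noise_sd: float = Field(ge=0.0)
    min: float
    max: float

    @model_validator(mode="after")
    def _check(self) -> "OutcomeModel":
        if not self.min < self.max:
            raise ValueError("min must be < max")
        return self


class RasrmLink(BaseModel):
    """Monotone quantile map from the shared latent severity to an r-ASRM score."""

    mean: float = 69.4
    sd: float = Field(default=35.0, gt=0)
    min: float = 10.0
    max: float = 150.0
    link_noise_sd: float = Field(default=0.65, ge=0.0)


class CohortSpec(BaseModel):
    """Full simulator configuration (marginals, correlation targets, outcomes, seed)."""

    n: int = Field(ge=0)
    seed: int = 0
    marginals: dict[str, MarginalSpec]
    uterine_prevalences: dict[str, float]
    rare_prevalence: float = Field(ge=0.0, le=1.0)
    rare_site_weights: dict[str, float]
    target_spearman: list[list[float]]
    duration: OutcomeModel
    blood_loss: OutcomeModel
    rasrm: RasrmLink = RasrmLink()

    @field_validator("uterine_prevalences")
    @classmethod
    def _prevalences(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != {"E", "R", "A"}:
            raise ValueError("uterine_prevalences needs exactly the keys E, R, A")
        if any(not 0.0 <= p <= 1.0 for p in v.values()):
            raise ValueError("prevalences must lie in [0, 1]")
        return v

    @field_validator("rare_site_weights")
    @classmethod
    def _weights(cls, v: dict[str, float]) -> dict[str, float]:
        if not v or any(w < 0 for w in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("rare_site_weights must be non-negative and sum to 1")
        return v

    @model_validator(mode="after")
    def _matrix(self) -> "CohortSpec":
        m = np.asarray(self.target_spearman, dtype=float)
        k = len(COMPONENTS)
        if m.shape != (k, k):
            raise ValueError(f"target_spearman must be {k}x{k} over {COMPONENTS}")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("target_spearman must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("target_spearman must have a unit diagonal")
        if np.any(np.abs(m) > 1.0):
            raise ValueError("target_spearman entries must lie in [-1, 1]")
        missing = [c for c in ("cyst", "adhesion", "pain") if c not in self.marginals]
        if missing:
            raise ValueError(f"marginals missing for components: {missing}")
        return self

    def spec_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def latent_correlation_from_spearman(rho: float) -> float:
    """Gaussian-copula latent correlation hitting a target Spearman rho:
    ``r = 2 sin(pi rho / 6)``."""
    if abs(rho) > 1.0:
        raise ValueError(f"Spearman rho must lie in [-1, 1], got {rho}")
    return 2.0 * math.sin(math.pi * rho / 6.0)


def _nearest_psd_correlation(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped projection back to a correlation matrix."""
    vals, vecs = np.linalg.eigh(matrix)
    vals = np.clip(vals, 1e-8, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _latent_matrix(spec: CohortSpec) -> np.ndarray:
    target = np.asarray(spec.target_spearman, dtype=float)
    latent = 2.0 * np.sin(np.pi * target / 6.0)
    np.fill_diagonal(latent, 1.0)
    eigs = np.linalg.eigvalsh(latent)
    if eigs.min() < -1e-10:
        warnings.warn(
            "latent correlation matrix is not positive semidefinite; "
            "repaired by nearest-PSD projection",
            stacklevel=2,
        )
        latent = _nearest_psd_correlation(latent)
        if np.linalg.eigvalsh(latent).min() < -1e-10:
            raise CohortSpecError("correlation matrix not PSD even after repair")
    return latent


def uterine_score_pmf(prevalences: dict[str, float]) -> tuple[list[int], list[float]]:
    """PMF of 3 x (number of lesion types present) for independent E/R/A.

    This is the Poisson-binomial law on {0, 3, 6, 9} induced by the three
    prevalences; its mean, 3 (pE + pR + pA), matches the published uterine
    score mean for the published prevalences.
    """
    probs = np.array([1.0])
    for p in (prevalences["E"], prevalences["R"], prevalences["A"]):
        probs = np.convolve(probs, [1.0 - p, p])
    return [0, 3, 6, 9], probs.tolist()


def _uterine_marginal(spec: CohortSpec) -> MarginalSpec:
    if "uterine" in spec.marginals:
        return spec.marginals["uterine"]
    values, probs = uterine_score_pmf(spec.uterine_prevalences)
    return MarginalSpec(kind="discrete_pmf", values=values, probs=probs)


def _severity_weights(latent: np.ndarray) -> np.ndarray:
    """Unit-variance equal weights over the component latents."""
    w = np.full(latent.shape[0], 1.0 / latent.shape[0])
    return w / math.sqrt(float(w @ latent @ w))


def _sample_latent(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    latent = _latent_matrix(spec)
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(len(COMPONENTS)))
    return rng.standard_normal((spec.n, len(COMPONENTS))) @ chol.T


def _scores_from_latent(spec: CohortSpec, z: np.ndarray) -> pd.DataFrame:
    u = special.ndtr(z)
    marginals = dict(spec.marginals)
    marginals["uterine"] = _uterine_marginal(spec)
    data = {
        name: marginals[name].ppf(u[:, i]) for i, name in enumerate(COMPONENTS)
    }
    return pd.DataFrame(data, columns=list(COMPONENTS))


def sample_component_scores(spec: CohortSpec) -> pd.DataFrame:
    """n x 4 integer component scores (cyst, adhesion, pain, uterine);
    deterministic given (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    return _scores_from_latent(spec, _sample_latent(spec, rng))


# ---------------------------------------------------------------------------
# Backfilling findings from sampled scores
# ---------------------------------------------------------------------------


def _diameter_for_score(score: int, rng: np.random.Generator) -> float:
    """Endometrioma diameter (1 dp) whose per-side score is exactly ``score``.

    Scores 1-4 come from (score-1, score]; the capped score 5 from (4, 9].
    Drawing on the 0.1 cm grid keeps the score <-> diameter round trip exact.
    """
    if score == 5:
        return float(rng.integers(41, 91)) / 10.0
    return float(rng.integers(10 * (score - 1) + 1, 10 * score + 1)) / 10.0


def _split_cyst_score(total: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Decompose a combined cyst score into (right, left, tubal sides)."""
    if not 0 <= total <= 16:
        raise CohortSpecError(f"cyst score {total} outside the 0-16 support")
    tubal_sides = 0 if total <= 10 else (1 if total <= 13 else 2)
    remainder = total - 3 * tubal_sides
    lo, hi = max(0, remainder - 5), min(5, remainder)
    right = int(rng.integers(lo, hi + 1))
    return right, remainder - right, tubal_sides


def backfill_exam(
    scores: Sequence[int],
    spec: CohortSpec,
    rng: np.random.Generator,
    patient_id: str = "synthetic",
) -> PatientExam:
    """Construct an exam whose flat-scheme component scores equal ``scores``.

    ``scores`` is (cyst, adhesion, pain, uterine).  Rare-site disease is drawn
    from the spec prevalence (it is not part of the sampled components).  The
    fine structure within a component (which sites, which regions, exact
    diameters) is synthetic and carries no clinical meaning beyond the score.
    """
    cyst, adhesion, pain, uterine = (int(s) for s in scores)
    if uterine % 3 != 0 or not 0 <= uterine <= 9:
        raise CohortSpecError(
            f"uterine score must be a multiple of 3 within 0-9, got {uterine}"
        )
    if not 0 <= adhesion <= 10:
        raise CohortSpecError(f"adhesion score {adhesion} outside 0-10")
    if not 0 <= pain <= 10:
        raise CohortSpecError(f"pain score {pain} outside 0-10")

    right_s, left_s, tubal_sides = _split_cyst_score(cyst, rng)
    sides = {}
    for name, s in (("right", right_s), ("left", left_s)):
        if s > 0:
            sides[name] = OvarySideFinding(
                side=name,
                cyst_diameter_cm=_diameter_for_score(s, rng),
                cyst_kind=CystKind.ENDOMETRIOMA,
            )
        else:
            sides[name] = OvarySideFinding(side=name)
    if tubal_sides:
        order = ["right", "left"] if rng.random() < 0.5 else ["left", "right"]
        for name in order[:tubal_sides]:
            sides[name] = OvarySideFinding(
                side=name,
                cyst_diameter_cm=sides[name].cyst_diameter_cm,
                cyst_kind=sides[name].cyst_kind,
                tubal_lesion=TubalLesion.HYDROSALPINX,
            )

    site_idx = rng.choice(len(ADHESION_SITES), size=adhesion, replace=False)
    adhesions = AdhesionMap({ADHESION_SITES[i]: True for i in site_idx})

    pain_values = {n: 0 for n in PAIN_REGION_NUMERALS}
    if pain > 0:
        if any(adhesions.sites[s] for s in DOUGLAS_AREA_SITES):
            peak_region = "V"  # posterior adhesions localise pain to the Douglas pouch
        else:
            peak_region = PAIN_REGION_NUMERALS[rng.integers(0, 7)]
        for numeral in PAIN_REGION_NUMERALS:
            pain_values[numeral] = int(rng.integers(0, pain + 1))
        pain_values[peak_region] = pain

    k = uterine // 3
    weights = np.array(
        [spec.uterine_prevalences[e] for e in ("E", "R", "A")], dtype=float
    )
    if k == 3:
        chosen = {"E", "R", "A"}
    elif k > 0:
        if weights.sum() == 0:
            weights = np.ones(3)
        picks = rng.choice(3, size=k, replace=False, p=weights / weights.sum())
        chosen = {("E", "R", "A")[i] for i in picks}
    else:
        chosen = set()
    nodules = ()
    if "E" in chosen:
        nodules = (float(rng.integers(10, 40)) / 10.0,)
    uterus = UterineFindings(
        retroverted="R" in chosen, adenomyosis="A" in chosen, nodules_cm=nodules
    )

    rare = RareSiteFindings()
    if rng.random() < spec.rare_prevalence:
        names = list(spec.rare_site_weights)
        probs = np.array(list(spec.rare_site_weights.values()), dtype=float)
        site = names[rng.choice(len(names), p=probs / probs.sum())]
        rare = RareSiteFindings(frozenset({site}))

    return PatientExam(
        patient_id=patient_id,
        right=sides["right"],
        left=sides["left"],
        adhesions=adhesions,
        pain=PainMap(pain_values),
        uterus=uterus,
        rare=rare,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort with outcomes; deterministic given (spec, seed)."""
    from .scoring import ENoduleScheme, e_score  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    provenance = {"spec_hash": spec.spec_hash(), "seed": spec.seed}
    if spec.n == 0:
        return Cohort(exams=[], provenance=provenance)

    z = _sample_latent(spec, rng)
    scores = _scores_from_latent(spec, z)
    exams = [
        backfill_exam(row, spec, rng, patient_id=f"S{i:05d}")
        for i, row in enumerate(scores.itertuples(index=False), start=1)
    ]
    e_totals = np.array(
        [e_score(exam, ENoduleScheme.FLAT3).e_score for exam in exams], dtype=float
    )

    def outcome(model: OutcomeModel) -> np.ndarray:
        noise = rng.normal(0.0, model.noise_sd, size=spec.n) if model.noise_sd > 0 else 0.0
        raw = model.slope * e_totals + model.intercept + noise
        return np.round(np.clip(raw, model.min, model.max), 1)

    durations = outcome(spec.duration)
    blood = outcome(spec.blood_loss)

    latent = _latent_matrix(spec)
    w = _severity_weights(latent)
    z_sev = z @ w
    link = spec.rasrm.link_noise_sd
    if link > 0:
        z_sev = (z_sev + rng.normal(0.0, link, size=spec.n)) / math.sqrt(1.0 + link**2)
    rasrm_marginal = MarginalSpec(
        kind="truncated_normal",
        mean=spec.rasrm.mean,
        sd=spec.rasrm.sd,
        min=spec.rasrm.min,
        max=spec.rasrm.max,
    )
    rasrm = rasrm_marginal.ppf(special.ndtr(z_sev))

    finished = [
        PatientExam(
            patient_id=exam.patient_id,
            right=exam.right,
            left=exam.left,
            adhesions=exam.adhesions,
            pain=exam.pain,
            uterus=exam.uterus,
            rare=exam.rare,
            outcomes=Outcomes(
                duration_min=float(d), blood_loss_ml=float(b), rasrm_score=int(r)
            ),
        )
        for exam, d, b, r in zip(exams, durations, blood, rasrm)
    ]
    return Cohort(exams=finished, provenance=provenance)


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _default_payload() -> str:
    return resources.files("nmse").joinpath("data/defaults.yaml").read_text()


def load_cohort_spec(payload: dict) -> CohortSpec:
    """Validate a plain dict (parsed YAML/JSON) into a CohortSpec."""
    try:
        return CohortSpec.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError -> domain error
        raise CohortSpecError(str(exc)) from exc


def default_cohort_spec(n: Optional[int] = None, seed: Optional[int] = None) -> CohortSpec:
    """The packaged default spec mirroring the published cohort summary."""
    payload = yaml.safe_load(_default_payload())
    if n is not None:
        payload["n"] = n
    if seed is not None:
        payload["seed"] = seed
    return load_cohort_spec(payload)
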