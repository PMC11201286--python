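# Methods

This note documents the scoring rules, the statistical machinery, the
synthetic-cohort model and the deliberate design choices behind `nmse`.

## Scoring model

The E-score is an additive severity index over five components; each
component is bounded and cheap to measure preoperatively.

**Cyst score.** Only endometriomas score. The per-side score is
`min(5, ⌈d⌉)` where `d` is the maximum diameter in cm to one decimal place
(for multi-cystic ovaries, the *total* of maximum diameters; the ceiling is
applied after summing). Non-endometrioma cysts are recorded (one-letter type
initial before the size) but score 0. Tubal lesions add 3 points per side —
tubes are only visible on ultrasound when enlarged, so any visible tubal
lesion is scored identically regardless of type.

**Adhesion score** counts sliding-sign-positive sites over a fixed ordered
list of ten locations (five cross-sectional: Rt.O-side, Rt.O-Ut., Inter O-O,
Lt.O-Ut., Lt.O-Side; five longitudinal: Upper ant., Mid. ant., Upper post.,
Mid.post., Lower post.).

**Pain score** is the maximum palpation NRS (integer 0–10) over seven regions
numbered I–VII around the cervix. Decimals are rejected at validation: the
instrument is an 11-point scale.

**Uterine score.** Retroversion and adenomyosis contribute 3 points each.
Endometriotic nodules (≥ 1 cm; smaller lesions are below the detection
convention and rejected at validation) contribute under two schemes:

- *flat3* (canonical): 3 points once if any nodule exists, regardless of the
  number of nodules. This reading — points per lesion *type* — keeps the
  uterine score within its stated 0–9 range.
- *sized_3_6_10*: 3/6/10 points per nodule for diameters in [1,2), [2,3),
  [3,∞) cm, cumulatively added. Band boundaries are half-open so every
  diameter maps to exactly one band; the total is then unbounded above.

**Rare-site score** is a flat 10 when any rare-site lesion exists, however
many sites are involved; a per-site cumulative mode is deliberately not
offered, keeping one canonical score.

There is no fixed global maximum: tubal and rare-site points extend the
nominal ~40-point core.

### Duration model

`DurationModel` is an affine map `y = slope·x + intercept` (minutes per
E-score point), fitted by ordinary least squares. The canonical coefficients
are `slope = 6.2995`, `intercept = 49.459`. *Erratum note:* a prose
illustration sometimes quoted with this model ("x = 19 → 175 min") is
inconsistent with the coefficients themselves, which give 169.15 min; the
package implements the equation and makes no attempt to force the prose
value. Slope and intercept are facility- and surgeon-specific; `fit` exists
precisely so users can recalibrate on local data.

## Rank statistics

Spearman's ρ is computed as the Pearson correlation of rank vectors. Two tie
dialects are provided:

- `average` (default): ties get the mean of their rank positions — the
  standard definition, identical to `scipy.stats.spearmanr`;
- `rank_eq`: ties all get the minimum (first) rank, reproducing a spreadsheet
  pipeline of RANK.EQ feeding CORREL. Spreadsheet ranking defaults to
  descending order, but reversing both rank vectors leaves the correlation
  unchanged, so ascending minimum-rank is the same statistic. Both vectors
  are ranked with the same dialect.

p-values use the large-sample two-sided t approximation with n−2 degrees of
freedom; no multiple-testing correction is applied. Correlations are kept at
full precision internally and rounded to 3 decimals only at presentation.
The `analyze` command computes the requested dialect and appends the other
one's columns whenever any cell differs by more than 0.001.

## r-ASRM comparison

The intraoperative r-ASRM score is implemented at component-point
granularity: peritoneal (≤ 6), endometrioma (≤ 40), cul-de-sac obliteration
(≤ 40), per-ovary adhesion category mapped {none: 0, <1/3: 4, 1/3–2/3: 8,
>2/3: 16}, tubal adhesions (≤ 32), total capped at 150. The full worksheet
(filmy vs dense, per-lesion sizes) is out of scope. Stage bins: I 1–5,
II 6–15, III 16–40, IV ≥ 41. The printed bins leave 41 unassigned
("16–40" / ">41"); 41 is assigned to stage IV, matching the standard
">40" convention.

## Synthetic cohort model

Real cohort data are unavailable, so the simulator emulates the published
validation cohort (n = 111) at the *component-score* level and backfills
findings:

1. **Copula.** A latent 4-dimensional Gaussian vector (cyst, adhesion, pain,
   uterine) is drawn with correlation `r = 2 sin(π ρ / 6)` applied entrywise
   to the target Spearman matrix — the standard identity that makes the rank
   correlation of the transformed marginals equal ρ. Non-PSD targets are
   repaired by eigenvalue clipping with a warning.
2. **Marginals.** Cyst/adhesion/pain scores come from integer-rounded
   truncated normals; the `mean` parameter is the mean of the *truncated*
   law and the location is solved numerically (naively centring the normal
   at the target would bias the adhesion mean by ≈ +0.19 because its 0–9
   support is asymmetric around 3.96). Defaults: cyst mean 6.32 on 0–12,
   adhesion 3.96 on 0–9, pain 6.07 on 1–10, with sds 3.0/2.3/2.4 chosen once
   from the printed ranges (≈ range/4; the source reports ranges, not sds).
   The uterine score is the Poisson-binomial law of 3×(#lesion types) induced
   by the prevalences E 0.522, R 0.396, A 0.243 (mean 3.483, consistent with
   the reported 3.51). Unreported between-component correlations default to a
   weak positive 0.3.
3. **Backfill.** Each score row is inverted into a concrete exam: the
   combined cyst score is split across sides (tubal lesions only for scores
   > 10); per-side diameters are drawn on the 0.1 cm grid strictly inside the
   band that ceils back to the score (capped score 5 → (4, 9]); adhesion
   sites are a uniform subset; one pain region carries the peak (region V
   preferred when posterior-wall adhesions are present, mirroring the
   clinical association between Douglas-pouch disease and posterior pain),
   the rest are ≤ peak; uterine lesion types are drawn weighted by
   prevalence; rare sites by prevalence 0.045 (weights vaginal 0.6,
   umbilical 0.2, inguinal 0.2, the relative frequencies reported). Scores
   round-trip exactly under the flat scheme by construction.
4. **Outcomes.** Duration = 6.2995·E + 49.459 + N(0, σ), truncated to
   [51, 421] min; blood loss analogously (slope 2.0, intercept 25.06,
   truncated to [0, 500] mL); the r-ASRM score is a monotone truncated-normal
   quantile map (mean 69.4, sd 35, clamped [10, 150]) of a shared latent
   severity (the normalized mean of the four component latents) perturbed by
   link noise. Noise constants are calibrated **once** at n = 50 000 so the
   default cohort reproduces the targeted rank correlations — duration σ =
   38.3 → ρ(E, duration) ≈ 0.724, blood σ = 29.0 → ≈ 0.400, link σ = 0.70 →
   ρ(E, r-ASRM) ≈ 0.760 — and recorded in `data/defaults.yaml`; they are
   stated defaults, not test knobs.

Everything is driven by one `numpy` Generator seeded from the spec, so equal
(spec, seed) gives byte-identical cohorts.

**What a green simulation test establishes — and what it does not.** The
simulator guarantees marginal and rank-correlation fidelity and exact score
round-trips; it does *not* model within-component clinical fine structure
(which sites adhere together, cyst laterality patterns, symptom VAS scores),
truncation-induced skew in real outcome distributions, or the case mix of a
surgical referral population. Recovering the configured ρ(E, duration) from
a generated cohort validates the analysis pipeline, not the clinical claim.

## Numerical choices and degenerate inputs

- Diameters are rounded half-up to one decimal on ingest; the ceiling used in
  scoring rounds the stored value to 6 decimals first so float fuzz at exact
  integers cannot bump a score.
- Constant vectors make Spearman undefined and raise; fewer than 3 pairs
  raise; OLS requires ≥ 2 distinct x values.
- The summary grammar is versioned (`nmse-summary/1`); the parser rejects
  other versions, reports character positions on malformed input, and
  recomputes the embedded `E=` total, failing on mismatch. Free-text labels
  are restricted to lowercase letters so they cannot collide with the
  `h.s`/`p.s` tubal abbreviations.
- CSV ingestion is lenient by default (per-row diagnostics, valid rows still
  load) because clinical CSVs are messy; `strict=True` aborts instead.

## Known limitations

- The summary dialect is this package's own; an original notation exists in
  appendix material that is not publicly deposited, so round-tripping against
  it cannot be verified.
- The intraoperative variant of the score (iE-score) is not implemented.
- Point weights are fixed; learning better weights from outcome data is
  explicitly out of scope.
- The r-ASRM link in the simulator is a statistical stand-in, not a model of
  how intraoperative staging actually maps to preoperative findings.
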