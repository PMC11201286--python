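# nmse — Numerical Multi-Scoring System of Endometriosis

`nmse` implements a preoperative severity score for endometriosis built
entirely from non-invasive findings: transvaginal ultrasound plus pelvic
examination. It is aimed at gynaecologic surgeons and clinical researchers who
need to (a) quantify disease severity *before* surgery, (b) share findings in
a compact notation, and (c) predict surgical duration for theatre planning.

## The score

A patient's **E-score** x is the sum of five component scores read off a
"Physical Finding Map":

| Component | Rule | Range |
|---|---|---|
| Cyst score | per ovary `min(5, ⌈diameter cm⌉)` for an endometrioma, summed; + 3 per side with a tubal lesion (hydro-/pyosalpinx) | 0–10 (+0–6 tubal) |
| Adhesion score | number of sliding-sign-negative (adherent) sites out of 10 canonical locations | 0–10 |
| Pain score | highest palpation NRS over 7 pelvic regions (I–VII) around the cervix | 0–10 |
| Uterine score | 3 points per lesion type: retroversion (R), adenomyosis (A), endometriotic nodule ≥ 1 cm (E); myoma noted, never scored | 0–9 |
| Rare-site score | flat 10 if any rare-site lesion (intestinal, bladder, ureteral, vaginal, …) | 0 or 10 |

An alternative **size-graded nodule scheme** scores each E nodule 3/6/10
points for diameters in [1,2), [2,3), [3,∞) cm, cumulatively.

Surgical duration is predicted by the affine model `y = 6.2995·x + 49.459`
minutes. Cohort validation uses Spearman rank correlations, with both the
standard tie-averaged ranks and a spreadsheet dialect (`rank_eq`: ties share
the minimum rank), plus an r-ASRM (revised American Society for Reproductive
Medicine) comparison: component points capped at 150, stages I 1–5, II 6–15,
III 16–40, IV ≥ 41.

Because real patient data are not publicly available, the package ships a
seeded Gaussian-copula simulator that reproduces the published cohort's
component-score marginals and targeted rank correlations, and backfills
concrete exams whose scores round-trip exactly.

## Worked example

```python
from nmse import worked_example, e_score, serialize_summary, ENoduleScheme
from nmse.analysis import CANONICAL_DURATION_MODEL

exam = worked_example()     # right endometrioma 6.5 cm, left 2.4 cm, 7 adhesions,
                            # peak pain 8 (Douglas pouch), adenomyosis + 2.6 cm nodule
b = e_score(exam, ENoduleScheme.FLAT3)
print(b.cyst_score, b.adhesion_score, b.pain_score, b.uterine_score, b.rare_score)
print("E =", b.e_score)
print(serialize_summary(exam))
print(f"{CANONICAL_DURATION_MODEL.predict(b.e_score):.1f} min")
```

prints

```
8 7 8 6 0
E = 29
Cy R6.5/L2.4 | Ad7/10 | P8@V | Ut A,E2.6 | Rare - | E=29
232.1 min
```

i.e. a combined cyst score of 8 (right capped at 5, left ⌈2.4⌉ = 3), seven
adherent sites, peak pain 8, uterine score 6 (A + E), total E-score 29, and a
predicted operation of about 232 minutes. Under the size-graded scheme the
2.6 cm nodule scores 6 instead of 3, so the total becomes 32.

## Command line

```sh
nmse simulate --n 111 --seed 7 --out cohort.csv   # synthetic cohort CSV
nmse score    --in cohort.csv --out scored.csv    # append score columns
nmse summarize --in cohort.csv                    # one summary line per patient
nmse analyze  --in cohort.csv --out corr.csv      # Spearman matrix vs outcomes
nmse predict  --escore 29                         # duration in minutes
```

## Acceptance script

`scripts/acceptance.py` rebuilds the worked example from the package's own
constructors and recomputes its headline quantities (total E-score, combined
and per-side cyst scores, adhesion, pain and uterine scores) at run time:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `nmse.exam` — domain types, validation, canonical site/region lists, map rendering
- `nmse.scoring` — component scores, E-score, variant schemes
- `nmse.summary` / `nmse.cohort_io` / `nmse.cli` — notation, CSV schema, CLI
- `nmse.analysis` — rank correlations, duration model, r-ASRM, descriptives
- `nmse.simulate` — seeded synthetic-cohort generator

See `docs/methods.md` for the statistical model, simulator assumptions and
design decisions.
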