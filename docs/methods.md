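# Methods

## The instrument

The package implements a 30-item deficit-accumulation frailty index.  A
*deficit* is any symptom, disease, disability or laboratory abnormality on
the item list; each item is coded on [0, 1] by an ordered scheme whose
weights must start at 0 (absent), end at 1 (fully present), increase
strictly and lie on the admitted grade set {0, 0.25, 0.33, 0.5, 0.66,
0.75, 1}.  The shipped registry (`src/frailkit/data/registry.yaml`) has 25
binary items, four three-level items (self-rated health, BMI, RBS, GDS)
and one four-level item (blood pressure: 0/0.33/0.66/1).  Users may supply
a replacement registry; it is validated against the same invariants.

The index for a subject is

FI = Σ(non-missing weights) / (30 − n_missing),

so missing items shrink the denominator rather than being imputed.  A
minimum completeness of 24/30 answered items (80%, a common
deficit-index convention) is required by default — below it the index is
refused rather than computed on a degenerate denominator.  The bound is
configurable (`min_items`).

Severity bands are right-inclusive: fit (0, 0.12], mild (0.12, 0.24],
moderate (0.24, 0.36], severe (0.36, 1], with FI = 0 assigned to fit.
Ties at a cut point therefore go to the less-severe class, read directly
from the defining inequalities.  The binary outcome for risk modelling is
frail ⇔ FI > 0.24, which coincides exactly with category ∈ {moderate,
severe} — a round-trip identity the test suite checks on a dense grid.
FI is carried at full floating precision; rounding happens only in report
writers.

## Measurement grading

The graded biomarker items state their labels but not always their
clinical thresholds, so the graders take configurable cut points with
documented defaults:

- **BMI** (kg/m², weight/height²): WHO adult bands; normal [18.5, 25) → 0,
  obese ≥ 30 → 1, everything else — underweight *and* overweight — → 0.5.
  Underweight is itself a deficit in elderly cohorts, which is why the
  grader is deliberately non-monotone below 18.5.
- **Blood pressure** (mmHg): WHO/ISH hypertension grades, <140/90 → 0,
  grade 1 (140–159 or 90–99) → 0.33, grade 2 (160–179 or 100–109) → 0.66,
  grade 3 (≥180 or ≥110) → 1; the worse of the systolic and diastolic
  grades governs, and up to three repeated readings are averaged per arm
  before grading.
- **Random blood sugar** (mmol/L): <7.9 → 0, [7.9, 15.0) → 0.5, ≥15 → 1.
  The half-open middle band closes the gap a printed "7.9–14.9 / 15.0 or
  more" convention leaves at [14.9, 15.0), so no input is unassignable.
- **GDS-15** (total 0–15): standard screening bands 0–4 / 5–9 / 10–15 for
  normal / moderate / severe depression.

All graders are step functions, weakly monotone in their argument (BP in
both arguments; BMI above 18.5), and always return a (label, weight) pair
that is a legal level of the corresponding registry item.

## Association statistics

- **Chi-square**: Pearson Σ(O−E)²/E on the full four-category table, no
  continuity correction, df = (r−1)(c−1); a flag marks expected counts
  below 5.  Zero marginal rows/columns are dropped; a table left with
  fewer than 2×2 positive margins is refused.
- **Odds, two conventions.**  `subgroup_frailty_odds` returns the
  within-level odds frail/fit on the binary collapse — the quantity many
  survey reports print as the "unadjusted OR" — with the log-odds normal
  interval exp(ln o ± 1.96·√(1/frail + 1/fit)).  `odds_ratio` is the
  textbook reference-contrast cross-product estimator with the Woolf
  interval, and an optional Haldane–Anscombe 0.5 correction for empty
  cells.  Both are exposed because the reference cohort's published
  unadjusted column is numerically the former, not the latter.
- **Logistic regression**: maximum likelihood via Newton iteration
  (equivalently IRLS; `statsmodels.Logit`, tolerance 1e-8, max 100
  iterations) on indicator expansions against declared reference levels.
  Standard errors from the inverse observed information; 95% bounds
  exp(β ± 1.959964·se); two-sided normal p-values.  Complete or quasi
  separation is detected and reported with the separating term named;
  rank-deficient designs are refused.  No Firth correction and no
  cluster-robust variance (deliberately: the reference analysis used
  neither), and no multiple-testing correction.
- **t-test**: pooled-variance two-sided Student t, df = n₁+n₂−2,
  accepting raw vectors or (n, mean, sd) summaries interchangeably.
- **Cronbach's alpha**: k/(k−1)·(1 − Σ item variances / total-score
  variance) with sample variances; undefined (refused) at zero total
  variance.
- **Prevalence intervals**: Wilson score by default (better behaved at
  small k), Wald available for comparison; the published figure's interval
  method is unstated, so Wilson is a package choice.

## Synthetic cohorts

**Table-faithful mode.**  The shipped defaults are the reference cohort's
published covariate-by-severity count matrices (nine covariates, column
sums 34/120/145/101, total 400).  Generation assigns each record its
category, then distributes each covariate's levels within each category
block by a seeded permutation — so every cross-tab equals its matrix
*exactly, for every seed*, while the joint covariate pattern varies with
the seed.  Only the margins are published, so covariates are drawn
**conditionally independent given category**; this is the minimal
assumption preserving every printed table, and it means joint-distribution
quantities (notably adjusted odds ratios) are *not* expected to match the
original cohort's.  FI is drawn uniformly within the record's severity
band, clipped to the observed range [0.05, 0.71]; alternatives are a
grid sampler restricted to FI values attainable as legal weight sums over
the 30 items, and a *deep* mode that synthesizes the 30 item-level
responses themselves (deficit sums on the half-integer grid of the band,
seeded), so the full coding-and-scoring path can be exercised end to end.
An optional continuous age column is drawn from a truncated normal
(mean 63.61, SD 8.73, range 55–100) for calibration displays; note the
realized mean of that truncated distribution is ≈ 66.3, not 63.61.

Under band-uniform sampling the expected cohort mean FI is
0.085·0.085 + 0.30·0.18 + 0.3625·0.30 + 0.2525·0.535 ≈ 0.305, a little
above the reference cohort's reported 0.28 — the true within-band FI
distribution is unknowable from printed counts, and no attempt is made to
skew the sampler toward it.

**Parametric mode.**  Covariates are drawn independently from declared
level probabilities; the frail outcome is Bernoulli(expit(β₀ + xβ)) with
known coefficients; FI is drawn uniformly within the outcome class's band.
The default spec uses the reference cohort's age/gender margins, its
adjusted odds ratios as true effects, and an intercept calibrated by
bisection so the marginal frail prevalence is 246/400.  This mode exists
for estimator calibration: parameter-recovery and coverage studies, not
realism.  What these cohorts do **not** emulate: covariate correlation,
measurement error in the raw biomarkers, item-level missingness patterns,
and any cluster structure — so passing tests certify the estimators and
the pipeline, not the epidemiology of any real population.

## Pipeline determinism and sizes

Reports (scored table, cross-tabs, odds/logistic table, prevalence
records, manifest) are written with fixed column order, fixed float
formatting (default 3 decimals) and no timestamps, so one config + seed
reproduces the bundle byte for byte.  The manifest echoes every resolved
cut point and a SHA-256 of the config.  Unscorable subjects are listed in
an errors file; a configurable tolerated fraction (default 0) decides
between failure and a partial report.

Simulation-based tests use 400-record table cohorts, recovery studies
n = 2,000 with 200–500 replicates (seconds on one CPU), chosen as the
smallest sizes at which the Monte-Carlo error of the checked quantities is
comfortably below the asserted tolerances.

## Known limitations

- No alternative frailty instruments (phenotype, FRAIL scale), no
  longitudinal trajectories, no imputation beyond the denominator
  adjustment.
- Severity cut points are fixed by convention; no data-driven calibration.
- The logistic layer reports separation rather than repairing it.
- Table-faithful cohorts reproduce margins, not joint structure; adjusted
  estimates on them are internally consistent but not comparable to the
  original cohort's adjusted estimates.
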