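# Methods

## Model

Poor COPD control is modelled as a Bernoulli outcome with

    logit(Pr) = α + β₁·a + β₂·b

where `a` is the annual count of dispensed rescue-inhaler canisters
(SABA, SAMA or both) and `b` the annual count of respiratory antibiotic
courses. Both slopes are constrained positive: the model's clinical
reading is that risk rises monotonically with either count. The inputs
are integers restricted to a bounded domain — a ∈ [0, 20], b ∈ [0, 5]
(126 cells) or a ∈ [0, 6], b ∈ [0, 2] (21 cells) — with raw counts
capped at the bounds. On a finite lattice the linear predictor
α + β₁a + β₂b takes distinct values in every cell whenever β₂/β₁ is not
a ratio of small integers reachable within the bounds; the package does
not rely on that argument analytically but verifies injectivity
numerically, the way the mapping is actually used: every cell's
probability is rounded to 14 decimal places (half-even) and the rounded
keys must be pairwise distinct. "Surjectivity" is reported as coverage
of the enumerated output set; coverage of the continuum (0, 1) is
impossible for a finite domain and is not claimed. Reverse inference
(probability → cell) is a key lookup at the same precision, with an
optional tolerance mode that returns the nearest cell and breaks exact
distance ties toward the lexicographically smaller (a, b), flagged in
the result.

### Default coefficients and calibration

The published account of the model does not print α, β₁, β₂ (they live
in an unavailable supplement), but it does print one anchor: the cell
(a=3, b=1) carries Pr = 95.53%. The package therefore treats
coefficients as explicit configuration and ships a default set obtained
by a deterministic pipeline: L1-penalized (LASSO) logistic regression
with 5-fold cross-validated penalty selection (seed 20240613) on the
bundled synthetic reference cohort, labels from the composite
poor-control rule, predictors unscaled; the fitted intercept is then
shifted so that Pr(3, 1) = 0.9553 exactly. The frozen values are

    α = −1.3966968859861533
    β₁ = 0.7140910977757319
    β₂ = 2.3164755183153978

Two calibration modes exist. The default shifts only the intercept,
preserving the fitted slopes. The alternative rescales all three
coefficients by a common factor, preserving the slope ratio; it is kept
as an option but not used for the defaults because scaling the slopes
up by the required factor (~1.9) pushes the top of the 126-cell grid
within 10⁻¹⁴ of probability 1, where 14-decimal rounding can no longer
separate cells — intercept shifting preserves both the anchor and full
injectivity. β₂ ≈ 3.2·β₁ in the defaults, i.e. one antibiotic course
moves the log-odds about as much as three canisters, consistent with
antibiotic burden being the stronger marginal driver.

### Fitting

`fit_penalized_logistic` wraps scikit-learn. `penalty_weight` is the
per-observation strength λ in (1/n)·Σ log-loss + λ·P(β) (mapped to
scikit-learn's C = 1/(nλ)); λ = 0 routes to an exact Newton solver
(`newton-cholesky`, tolerance 10⁻¹²) and equals the unpenalized MLE;
"cross-validated" selects λ over a 33-point logarithmic grid in
[10⁻⁴, 10⁴] by 5-fold stratified cross-validated deviance with the
spec's seed governing fold shuffling and the saga solver's sampling, so
repeated fits are bitwise identical. Quasi-separation at λ = 0 (|β| >
30 or non-convergence) is reported as a warning and answered with a
minimal ridge penalty (λ = 10⁻⁴) so the returned coefficients are
finite. Predictors are never standardized by default; an opt-in flag
standardizes internally and back-transforms the coefficients to the
count scale. `compare_regularizers` scores each fit by rank-based
concordance (AUROC) on the fitting cohort and counts nonzero slopes at
a 10⁻¹⁰ threshold.

## Deterministic clinical rules

All thresholds default to the published values and are plain integers
or probabilities:

| rule | default |
| --- | --- |
| high rescue use (H) | a ≥ 3 canisters/year |
| poor control | ≥1 moderate or ≥1 severe exacerbation, or a ≥ 3 |
| proxy phenotype from b | E if b ≥ 2, A1/B1 if b = 1, A0/B0 if b = 0 |
| Pseudomonas surveillance | uncapped b ≥ 5 AND Pr ≥ 0.99 |
| eosinophil gate for ICS | 100 cells/µL |
| alert thresholds | a ≥ 4, b ≥ 2, Pr > 0.50 (flag), Pr > 0.70 (priority) |

When both an explicit exacerbation history and the proxy `b` are
available, the history wins for phenotype assignment; `b` is a
fallback. The A-vs-B symptom distinction is deliberately collapsed into
the composite labels A0/B0 and A1/B1 — no symptom-scale inputs exist in
the model. The Pseudomonas rule reads the *uncapped* course count,
since the 21-cell domain caps b at 2 and would otherwise hide the
phenotype. Cross-system phenotype agreement is exact by construction:
the H cutoff (3) lies at or below both caps on a, and the proxy E
cutoff (2) at or below both caps on b, so capping never crosses a
boundary — this is the mechanism behind the perfect κ between the 126-
and 21-cell systems, and it is tested exhaustively over a ∈ [0, 40],
b ∈ [0, 10].

Treatment audit rules are encoded at the granularity of three
discrepancy patterns (ICS without eosinophilic support and without a
documented prior count ≥ 100; exacerbators on monotherapy or on
low-eosinophil ICS+LABA who should receive dual bronchodilation;
eosinophilic frequent exacerbators lacking ICS). Records without a
current eosinophil count are reported unauditable rather than erroring,
mirroring how such patients are excluded from guideline audits. The
full GOLD treatment algorithm is out of scope.

## Synthetic cohort generator

The generator emulates the reference validation cohort: n = 106, ages
truncated-normal 68.8 ± 8.2 on [40, 80], 72.6% male, 56.6% site 1,
phenotype mix 53 : 28 : 25 (A0/B0 : A1/B1 : E) and the published
conditional structure — 6/53, 8/28 and 7/25 high rescue users per
phenotype; consultation rates per (phenotype × use level) chosen to
satisfy simultaneously the phenotype-by-consultation table
[[43,10],[11,17],[3,22]] and the use-by-consultation table
[[15,6],[34,51]]; multiple daily inhalation doses per phenotype
[[31,22],[7,21],[10,15]]; among exacerbators, 8/53 missing eosinophil
counts and 4/45 of the measured below 100 cells/µL. (A published
single-dose share of "58.5% (51/53)" is internally inconsistent; the
generator uses 31/53 = 58.5%, which also reconciles the row total and
the printed χ² of 8.662.) The 55.7% poor-control prevalence (59/106) is
emergent, not drawn: exacerbators (53) plus the 6 non-exacerbating high
users equal 59.

In quota mode these counts are hit exactly (largest-remainder
apportionment for the phenotype margin, exact subset draws within
groups); in sampling mode every patient is an independent draw from the
same conditional probabilities, converging to the targets as n grows.
Raw counts span a ∈ [0, 40] (low users uniform on 0–2, high users
3 + geometric) and b ∈ [0, 10] (coupled to the exacerbation count with
±1 slack plus occasional unlinked bronchitis courses), so capping is
genuinely exercised. The slack is also what makes proxy-based
phenotyping imperfect, as in real data. Internal consistency — the
drawn phenotype always equals the label recomputed from the generated
history — is asserted at generation time.

What the generator does *not* emulate: longitudinal trajectories,
comorbidity, adherence, site-level effects beyond the label, or the
real joint distribution of (a, b) beyond the published margins. Tests
passing on synthetic cohorts therefore demonstrate the engine's
correctness and internal consistency, not clinical performance on real
patients; the published real-cohort metrics (AUROC 0.978, κ = 0.70
versus clinicians) require the original data and are deliberately not
asserted anywhere.

Dispensing aggregation counts one canister per rescue dispensation
unless a quantity field says otherwise, and one antibiotic course per
(date, drug) episode, filtered to respiratory indications when an
indication is recorded; code lists default to ATC-style prefixes
(R03AC/R03BB rescue, J01 antibacterial) and are configurable because no
code system is mandated by the data model.

## Evaluation statistics

- **Cohen κ**: unweighted, with a two-sided p-value from the
  large-sample normal approximation κ/SE₀ (Fleiss null standard error).
  The degenerate case of two identical constant sequences returns
  (1.0, 1.0).
- **χ²**: Pearson, no continuity correction — validated choice: it
  reproduces all four published statistics (6.691, 4.810, 35.873,
  8.662) from the printed tables; a Yates-corrected 2×2 would not.
  Computed via `scipy.stats.chi2_contingency` and cross-checked in the
  tests against an explicit expected-counts oracle.
- **Trend**: linear-by-linear association, (n−1)·r² with integer scores
  by default, referred to χ²₁; compared against a permutation oracle in
  the tests.
- **Likelihood ratios**: LR⁺ = Se/(1−Sp) with an explicit +∞ sentinel
  (serialized "inf") when specificity is exactly 1; undefined ratios
  (e.g. PPV with no positive calls) are NaN, never exceptions.
- **Bootstrap**: percentile intervals over patient resamples, seeded;
  failing resamples are skipped and counted.
- **Power**: Monte-Carlo over refits of the two-predictor model. Each
  replicate draws covariates from the synthetic spec's distribution and
  the outcome from the supplied truth, then tests the model-level
  likelihood-ratio statistic (both slopes vs intercept-only, χ²₂) at
  level α. The model-level criterion was chosen over per-coefficient
  Wald tests because its size under the null equals the nominal level
  (a conjunction of two Wald tests has size ≈ α²), which is also what a
  "model-level power" figure refers to. The published power value
  (92.4%) depends on the real covariate distribution and is validated
  by properties (size under the null, monotonicity in effect and n,
  saturation) rather than by that number.
- **Events per variable**: round(round(n·train)·prevalence)/p, the
  integer-rounded bookkeeping that yields 23.5 for (106, 0.80, 0.557, 2).

## Interoperability

Bundles are FHIR-R5-shaped JSON dictionaries (RiskAssessment,
DetectedIssue, Condition, Provenance), emitted per patient or as an
NDJSON stream. DetectedIssue is a pure function of (a_raw, b_raw, Pr,
audit flags, thresholds); Provenance embeds the model version and a
SHA-256 digest of the coefficient values. Condition codings are
placeholder SNOMED-CT-style codes behind a configuration hook. The
official HL7 validator is an external tool and is not run; the emitted
documents are schema-shaped, not certified.

## Numerical choices and limitations

- Probabilities are clamped into the open interval (0, 1) at the float
  boundary so extreme cells never collapse to exactly 0 or 1.
- Rounding for grid keys is half-even on the decimal expansion of the
  double; the stated 14-decimal precision is configurable in [1, 17].
- Grid verification is numeric at stated precision; no symbolic
  irrationality argument is attempted.
- Problem sizes in the test suite (e.g. parameter recovery at n = 5000,
  power at 500–2000 replicates, sampling-mode convergence at n = 10⁵,
  bootstrap coverage over 300 meta-replicates) were chosen as the
  smallest sizes at which the asymptotic properties under test are
  comfortably resolved.
- The default coefficients are fitted to *synthetic* data; they are a
  working default, not clinical truth. Users with access to the
  original supplement's coefficients can supply them via the JSON
  coefficient config (`--coeffs`) and will reproduce the anchor cell
  identically.
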