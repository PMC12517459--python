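# copdgrid

Deterministic, bijective risk grids for COPD control assessment from
routine prescribing counts.

## The problem

In primary care, spirometry and symptom scores are recorded too
irregularly to drive systematic detection of poorly controlled chronic
obstructive pulmonary disease (COPD). Two quantities, however, are in
every structured EHR: the number of rescue-inhaler canisters (SABA/SAMA)
dispensed per year, `a`, and the number of respiratory antibiotic
courses per year, `b`. `copdgrid` implements a transparent risk engine
built only on those two counts, aimed at clinicians, EHR integrators and
health-services researchers who need risk stratification without machine
learning opacity.

## The model

The probability of poor control is a plain logistic equation,

```
logit(Pr) = α + β₁·a + β₂·b,      β₁, β₂ > 0
```

evaluated on a *bounded integer domain*: a ∈ [0, 20] × b ∈ [0, 5]
(126 cells, high resolution) or a ∈ [0, 6] × b ∈ [0, 2] (21 cells,
streamlined); raw counts above the bounds are capped. Because the domain
is finite, the map cell → Pr can be checked exhaustively: with the
default coefficients all 126 probabilities are distinct at 14 decimal
places, so every probability inverts back to its unique (a, b) cell —
forward risk estimation and reverse phenotype inference are both exact.

On top of the grid sit deterministic clinical rules:

- **Phenotype** — GOLD-style categories A0/B0 (no exacerbations),
  A1/B1 (one moderate), E (≥2 moderate or ≥1 severe), assigned from the
  exacerbation history or from `b` as a proxy, crossed with rescue-use
  level H (a ≥ 3) / L.
- **Poor control** — any moderate or severe exacerbation, or a ≥ 3
  canisters/year.
- **Pseudomonas surveillance** — uncapped b ≥ 5 together with Pr ≥ 0.99.
- **Treatment audit** — eosinophil-gated concordance checks of the
  maintenance regimen (ICS not recommended below 100 cells/µL without a
  documented prior high count; escalation to dual bronchodilation;
  triple-therapy candidacy).

The package also ships a synthetic cohort generator that reproduces the
reference study cohort's structure (n=106, phenotype mix 53/28/25,
55.7% poor control, and its published contingency tables, exactly in
quota mode), a penalized-regression fitting and regularizer-comparison
toolkit, an evaluation suite (Cohen κ, χ², trend tests, likelihood
ratios, bootstrap CIs, Monte-Carlo power), and FHIR-R5-shaped JSON
export (RiskAssessment / DetectedIssue / Condition / Provenance) with
threshold-driven alerts.

## Worked example

```sh
$ copdgrid predict --a 3 --b 1
{
  "a": 3,
  "b": 1,
  "capped": false,
  "pr": 0.9553,
  "phenotype": "A1/B1-H"
}
```

A patient dispensing 3 rescue canisters and 1 respiratory antibiotic
course per year maps to the cell (3, 1): a 95.53% predicted probability
of poor control and the phenotype "GOLD A1/B1 with high rescue use".

```sh
$ copdgrid verify --system 126
{
  "cells": 126,
  "distinct_outputs": 126,
  "injective": true,
  "surjective_over_codomain": true,
  "collisions": []
}
```

All 126 cells produce distinct probabilities at 14 decimals, so reverse
lookup is well defined. The same check on `--system 21` gives 21/21.

From Python, a whole panel at once:

```python
>>> import copdgrid as cg
>>> cohort = cg.generate_cohort(cg.CohortSpec(), seed=1)   # n=106
>>> report = cg.run_population_report(cohort)
>>> report.head(3)[["id", "a", "b", "pr", "expanded_phenotype", "alert"]]
  id    a  b        pr expanded_phenotype  alert
P097    5  4  0.999989                E-H   True
P082    1  5  0.999982                E-L   True
P100    4  4  0.999978                E-H   True
>>> round(report["poorly_controlled"].mean(), 3)
0.557
```

The report ranks the panel by predicted risk; the top rows are frequent
exacerbators with heavy antibiotic exposure (P082 additionally carries
the Pseudomonas-surveillance flag), and the poor-control prevalence of
the synthetic reference cohort is 55.7%.

## Layout

| module | contents |
| --- | --- |
| `copdgrid.model` | coefficients, forward prediction, calibration, penalized fitting, regularizer comparison |
| `copdgrid.phenotype` | capping, phenotype/control/Pseudomonas/audit rules |
| `copdgrid.grid` | grid enumeration, bijectivity verification, inversion |
| `copdgrid.cohort` | synthetic cohorts, dispensing aggregation, eligibility |
| `copdgrid.metrics` | κ, χ², trend, correlations, bootstrap, power, reports |
| `copdgrid.fhir`, `copdgrid.io`, `copdgrid.cli` | FHIR-shaped export, cohort I/O, panel reports, CLI |

See `docs/methods.md` for the statistical methodology and design notes.
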