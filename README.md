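# cvdlife

Multistate life tables and meta-polygenic scoring for estimating total
and cardiovascular-disease-free life expectancy (LE) by genetic and
lifestyle risk.

## The problem

How many years of life, and how many years *free of cardiovascular
disease (CVD)*, does a 40-year-old stand to gain from a favourable
genetic background or lifestyle?  Answering this requires two pieces of
machinery that this package implements as a tested, reusable pipeline:

1. **A meta polygenic risk score (meta-PRS) for overall CVD.**
   Candidate scores are built from many GWAS summaries by clumping and
   thresholding (externally computed weight files, e.g. lassosum or
   PRS-CS output, plug in alongside); the candidate most strongly
   associated with incident disease is kept per GWAS; European and
   East-Asian scores for the same trait are integrated or not by AIC;
   and the trait-specific scores are stacked with a cross-validated
   elastic-net logistic model.  The stacked model expands back to a
   single per-variant weight vector.

2. **A population-based multistate life table** over the illness–death
   model with transitions (1) CVD-free → incident CVD, (2) CVD-free →
   non-CVD death, (3) CVD → death.  Its three ingredients are estimated
   from a cohort: pooled age-specific Poisson transition rates
   λ̂ᵢ(x) (log person-time offset), 5-year age-specific prevalence
   π_g(x) of each risk category per state, and per-transition Cox
   hazard ratios HR_{i,g} (age time-scale with left truncation for
   transitions 1–2; time since onset, age at onset adjusted, for
   transition 3).  Group-specific rates come from the calibration

   λ_{i,g}(x) = λ̂ᵢ(x) · HR_{i,g} / Σ_h π_h(x) · HR_{i,h},

   which preserves the pooled rate exactly.  With constant hazards
   within each one-year interval, the competing exits have exact
   probabilities q₁ = (λ₁/Λ)(1−e^{−Λ}), q₂ = (λ₂/Λ)(1−e^{−Λ}),
   Λ = λ₁+λ₂, and q₃ = 1−e^{−λ₃}.  Occupancies advance from a radix
   entirely CVD-free at age 40 to table closure at 90; person-year
   sums give total LE, CVD-free LE and LE with CVD (a 40–90 temporary
   life expectancy).  A 10,000-run parametric bootstrap (Gaussian on
   Poisson coefficients and log-HRs, Dirichlet on prevalence, draws
   shared across groups) yields percentile 95% CIs for every quantity
   and paired CIs for between-group differences.

Because individual-level biobank data are restricted, the package
ships a first-class synthetic-data module: cohorts drawn from Gompertz
baseline hazards times group hazard ratios (defaults emulate a large
Chinese biobank testing set: ~70k adults aged 30–79, ~28–31% incident
CVD over 10–14 years, genetic-risk HRs 1.2/1.63, 1.01/1.11, 1.07/1.25
for the three transitions), plus a continuous-time Kolmogorov-forward
oracle giving each group's exact life expectancies, and a genetics
generator with known trait architectures for validating the meta-PRS
construction end to end.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_build_metaprs.py  --seed 1
python analysis/03_fit_transitions.py
python analysis/04_life_expectancy.py --seed 1
```

Step 01 draws the default 70,000-person cohort (31.4% incident CVD,
21.2% deaths with seed 1) and records the oracle group life
expectancies.  Step 03 prints the fitted ingredients, e.g. transition-1
Cox hazard ratios `intermediate=1.23, high=1.67` against generative
values 1.20/1.63.  Step 04 prints the life tables' headline numbers:

```
life expectancy at age 40 (table closed at 90; 10000 bootstrap runs)
  low           total 37.73 (37.44-38.00)  CVD-free 30.64 (30.31-30.95)  free share 81.2%   [truth 37.49 / 30.50]
  intermediate  total 36.32 (36.15-36.50)  CVD-free 28.79 (28.60-28.99)  free share 79.3%   [truth 36.40 / 28.85]
  high          total 34.18 (33.92-34.45)  CVD-free 25.78 (25.50-26.07)  free share 75.4%   [truth 34.13 / 25.88]
differences vs high genetic risk (paired bootstrap):
  low           total +3.54 (3.17-3.90)  CVD-free +4.85 (4.45-5.26)
```

Reading: a 40-year-old in the lowest genetic-risk quintile is expected
to live 3.5 more years in total, and 4.9 more years free of CVD, than
one in the top quintile — the CVD-free gain exceeds the total gain
because low genetic risk mostly delays disease onset rather than
postponing death after onset.  The bracketed truths come from the
continuous-time oracle; every estimate's 95% CI covers it.

Published three-sheet input workbooks (Poisson coefficients, group
prevalences, Cox coefficients) can be fed directly to the engine via
`cvdlife.io.read_lifetable_workbook` with a column-mapping config; a
`cvdlife` CLI (`simulate`, `build-prs`, `fit-transitions`, `lifetable`,
`bootstrap`, `report`) wraps the same stages for shell use.

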