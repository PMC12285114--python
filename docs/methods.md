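# Methods

## The illness–death model and its life table

Individuals occupy one of three states — CVD-free, living with CVD,
dead — with transitions 1 (free → CVD), 2 (free → non-CVD death) and
3 (CVD → death).  Only first entries count and there is no recovery
(backflow).  The life table is Markov in current age: transition-3
intensity depends on attained age, not on disease duration.  The
engine assembles, for each risk category g and each one-year age
interval [x, x+1) between 40 and 90:

* a pooled rate λ̂ᵢ(x) from Poisson regression of person-period event
  counts on an age basis with a log person-time offset, evaluated at
  interval midpoints;
* category prevalence π_g(x) per state from person-year tabulation in
  5-year bands (each integer age inherits its band's value);
* Cox hazard ratios HR_{i,g} with the reference category fixed at 1.

Group rates follow the marginal-preserving calibration
λ_{i,g}(x) = λ̂ᵢ(x)·HR_{i,g}/Σ_h π_h(x)·HR_{i,h}; the
prevalence-weighted mean of the group rates reproduces the pooled rate
identically (tested to 1e-12).  Within-year hazards are constant, so
the free-state competing exits use the exact exponential split rather
than a half-rate approximation — this makes the discretisation
oracle-checkable: on exact Gompertz inputs the 1-year table is within
0.1 year (measured ≈ 0.01) of a continuous-time solution, and the gap
shrinks as the internal step is refined.  New CVD entrants face
half-interval transition-3 risk in their onset year; person-years are
trapezoidal; the table closes at 90 with no open interval, so all life
expectancies are 40–90 temporary expectancies (≤ 50 years).

Why this reconciliation of time scales: the transition-3 Cox model is
fitted on time since onset (with age at onset as a covariate) because
that is the natural scale for post-onset survival, but the life table
needs an age-indexed intensity.  The engine therefore refits the
pooled transition-3 *rate* on the age scale from the CVD-state
person-period data and applies the duration-scale Cox HRs to it.  When
post-onset hazards are log-linear in attained age (as in the
generator), the duration-scale model with a log-linear onset-age
adjustment is exactly proportional, so the HR transfers without bias;
for other hazard shapes this is an approximation the Markov table
already makes.

## Uncertainty

The parametric bootstrap redraws, per run: Poisson coefficient vectors
from Gaussians with the GLM covariance (Cholesky; diagonal fallback if
singular); log-HR vectors from Gaussians with the Cox covariance; and
each (band, state) prevalence column from a Dirichlet with
concentrations equal to the observed person-years (cells with no
person-time stay at their point values, so point-estimate-only inputs
give zero-width intervals).  All draws are shared across groups within
a run, so percentile CIs for between-group differences reflect paired
uncertainty.  The default is 10,000 runs, vectorised over a leading
run dimension, which takes about a second.  Calibration was verified
by simulation: across 200 independent cohorts of 6,000 (500-run
bootstraps), the 95% intervals covered the oracle group life
expectancies ~94% of the time.

## Meta-PRS construction

Stage 1 builds candidate scores per GWAS by greedy LD clumping
(ascending p; retain if r² with every retained variant within the
window is below threshold) followed by p-value thresholding.  The
default grid is r² ∈ {0.1, 0.2, 0.5}, window 250 kb, p ∈ {5e-8, 1e-6,
1e-4, 1e-2, 0.1, 0.5, 1}, chosen to span standard practice; it is
fully configurable, and externally computed weight files (lassosum,
PRS-CS) enter as additional candidates.  Strand-ambiguous (A/T, C/G)
variants are dropped at harmonisation since they cannot be oriented
without strand information; effect alleles matching the panel's other
allele flip the weight sign.

Stage 2 selects, per GWAS, the candidate with the largest absolute
Wald z in a covariate-adjusted logistic model of the training outcome
(ties to the first by input order; candidates with separation or zero
variance are skipped with a warning).  For traits with separate
European and East-Asian GWAS, logistic models with the EUR score, the
EAS score, and both are compared by AIC; near-collinear pairs
(|r| > 0.999) fall back to the better single-score model.

Stage 3 stacks the standardized trait scores with an elastic-net
logistic model: seeded stratified 10-fold cross-validation over
l1_ratio ∈ {0.1, 0.5, 0.9} × 10 penalty strengths, selecting the
minimal mean validation deviance with near-ties (within 0.1%)
resolved toward the stronger penalty — this parsimony tie-break is
what lets a signal-free outcome collapse to the all-zero solution
(returned with a warning rather than an error).  The stacking model is
covariate-free; covariates enter only the selection steps, since
downstream association models adjust for them anyway.  The fitted
model expands to a single per-variant weight vector
Σ_t coef_t · w_{t,v}/sd_t (for AIC-integrated traits, the two ancestry
files are first merged with the integration model's coefficients);
applying the expansion to any panel reproduces the stacked score up to
an affine transform (tested at correlation 1).

## Synthetic study conditions

The cohort generator emulates the testing set of a large Chinese
biobank: n = 70,000 (configurable), entry ages uniform on 30–79, 40.2%
men, administrative censoring 10–14 years after entry, a 20/60/20
low/intermediate/high genetic-risk split, and transition hazard ratios
(1, 1.20, 1.63), (1, 1.01, 1.11), (1, 1.07, 1.25) taken from the
fitted Cox models such an analysis reports for women.  Baseline
hazards are Gompertz λᵢ(x) = aᵢ·e^{bᵢx} with a₁ = 3.0e-4, b₁ = 0.070
(CVD incidence), a₂ = 1.2e-5, b₂ = 0.095 (non-CVD death), a₃ = 2.0e-4,
b₃ = 0.085 (post-CVD death) — chosen once so that roughly 30% of the
cohort develops CVD over follow-up, crude incidence is ≈ 0.026–0.03
per year at the mid-follow-up mean age, and 40–90 temporary life
expectancies land in the high 30s with a 72–81% CVD-free share,
matching the published pattern.  Latent event times come from the
Gompertz inverse CDF; the earlier of the transition-1/2 times wins;
post-onset survival is drawn Markov in attained age.  Each
individual's uniforms occupy one row of a single seeded draw matrix,
so histories are stable as n grows.

The oracle integrates the Kolmogorov forward equations
dP_free/dx = −(λ₁+λ₂)P_free, dP_cvd/dx = λ₁P_free − λ₃P_cvd with
fixed-step RK4 (default step 0.01 year), carrying the occupancy
integrals as extra state so life expectancies converge at fourth
order.

The genetics generator draws binomial dosages at frequencies 0.05–0.5,
sparse-normal trait effects with a shared causal set and configurable
cross-trait correlation, per-variant GWAS noise with standard errors
implied by a stated GWAS sample size, and EUR/EAS effect attenuation.
What it deliberately does not emulate: realistic LD beyond
block-exchangeable panels, population stratification, region/cluster
structure, nested case–control sampling, lifestyle change over
follow-up, and non-proportional hazards.  Passing tests therefore
demonstrate correctness of the estimators and engine under the stated
model, not robustness to those real-data complications.

## Numerical and design choices

* Quantile categorisation is rank-based (cut at ⌈k·n/5⌉ with stable
  tie-breaking by input order), so it commutes with monotone
  transforms and needs no interpolation convention.
* Physical activity exactly at the stratum median counts as
  favourable ("lower half" read strictly); a flag flips this.
  Former smokers who quit by choice are favourable; illness-quitters
  are not.
* Cox fits use Efron tie handling.  Unweighted fits go through the
  partial-likelihood implementation in statsmodels (fast at biobank
  scale); the IPW-weighted transition-3 refit uses lifelines, which
  supports case weights with robust variance.  IPW weights are
  stabilised and truncated at the 1st/99th percentiles.
* The Poisson age basis is log-linear (Gompertz-type) by default, with
  quadratic and natural-cubic-spline options; a workbook reader adapts
  to whatever basis its coefficient rows encode via a mapping config.
* Degenerate cases: zero rates are handled by limits (q → 0); all-zero
  scores are rejected at standardisation; cohorts with no CVD
  person-time fall back to free-state prevalence with a warning; empty
  prevalence bands inherit the nearest non-empty band.
* Problem sizes in the validation suite — 20 replicate cohorts of
  20,000 for end-to-end recovery, 200 cohorts of 6,000 with 500-run
  bootstraps for coverage — were chosen as the smallest scales at
  which the statistical assertions (3-SE recovery, 90–99% coverage)
  are stable across seeds.

## Known limitations

The engine's published-workbook mode inherits whatever discretisation
and bootstrap conventions the workbook's source used; reproduced
life-expectancy numbers can differ at the ~0.1-year level from values
printed elsewhere.  The Markov (age-indexed) treatment of post-CVD
mortality ignores duration dependence; the generator offers only the
Markov form, so this approximation is untested against
duration-dependent truth.  The meta-PRS stage treats GWAS variants as
LD-independent once clumped and does not re-implement lassosum or
PRS-CS.  Life expectancies condition on being CVD-free at the index
age (the radix is entirely in the free state).
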