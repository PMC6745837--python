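# Methods

## Problem and data model

A cohort is one row per patient: the hospital where resection took place, a
binary indicator of adjuvant chemotherapy (ACT) started within 16 weeks of
surgery, and categorical covariates (age group, sex, SES quintile, Charlson
comorbidity, T stage, N stage, histological grade, lymphovascular invasion,
lymph-node harvest) plus an integer length of stay. Unknown/NA levels (SES
unknown, LVI NA, grade unstated, node-harvest unknown) are first-class
category levels, not missing data, so every denominator is preserved. A
hospital table carries three binary system-level attributes: teaching
status, comprehensive-cancer-centre status, and on-site medical oncology.

## Rate variation and the Monte Carlo null

The hospital-specific rate is r_h = k_h/n_h; inter-hospital variation is
summarized by the coefficient of variation CV = SD(r_h)/mean(r_h), with the
sample SD (n−1 denominator; a set of hospitals is treated as a sample) and
each hospital weighted equally. The CV is computed over all hospitals with
at least one case by default (`min_cases` configurable; small-hospital
exclusion is a disclosure-control convention, not an analytic requirement).

Finite volumes make a nonzero CV inevitable. The chance component is
quantified by simulation: each iteration draws k_h ~ Binomial(n_h, p̂)
independently per hospital, where p̂ is the pooled observed rate and n_h are
the actual volumes, and records the CV of the simulated rates (1000
iterations by default). The expected CV is the mean of the simulated CVs;
its 95% interval is the empirical 2.5/97.5 percentile band (the simulated
CV distribution is right-skewed, so percentiles rather than a normal
approximation). Iterations in which every count is zero leave the CV
undefined; they are excluded and counted (`n_degenerate`). The nonrandom
component is the raw difference CV_obs − E[CV | null], reported even when
negative, together with a flag for whether CV_obs lies inside the null
band.

Binomial CIs for individual and pooled rates use the Wilson score interval
by default; Wald is available as an option.

## Case-mix adjustment

The outcome model is a maximum-likelihood logistic regression of treatment
on age group, sex, SES quintile, Charlson score, length of stay
(continuous, per day), T stage, N stage, LVI and grade, reference-coded
(references: age 20–49, female, SES 1, Charlson 0, T3, N1, well–moderate
grade, LVI no). Patients with unknown SES are dropped with a warning by
default (configurable to own-category); node harvest is not in the model.
Complete separation is detected up front (a level whose patients are all
treated or all untreated) and raised as an error naming the covariate.

**Adjusted hospital rates** use indirect standardization: expected_h is the
mean model-predicted probability over hospital h's own patients, and
adjusted_h = (observed_h/expected_h) × pooled rate. Indirect
standardization is the stable choice for small providers (direct
standardization of a 5-case hospital to the provincial case mix would
extrapolate wildly). Uncertainty comes from a parametric bootstrap: each
replicate (i) redraws coefficients from N(β̂, V̂) and (ii) redraws patient
outcomes from the implied probabilities, where "implied" includes a
per-hospital log-odds offset calibrated so each hospital's implied mean
equals its observed rate (with a (k+0.5)/(n+1) continuity correction at
the boundaries). Without that offset the redrawn outcomes would carry no
hospital deviation and the interval for an outlying hospital would not even
cover its own estimate. Percentile 95% intervals are reported per hospital.
The bootstrap is conditional on the selected model and, for the adjusted
pared-mean below, on the selected hospital set; it does not propagate
selection/re-ranking uncertainty.

**System-level factor effects** come from one logistic model per factor
(factor + covariates) via marginal standardization: g(level) is the mean
predicted probability over the full analysis cohort with the factor set to
that level; the adjusted RR is g(1)/g(0), with percentile CIs from a
coefficient-only parametric bootstrap. With no covariates this reduces
exactly to the unadjusted RR (the saturated two-group logit reproduces the
group rates). Unadjusted RRs carry Katz log-scale CIs. Risk ratios are
derived from the logistic model rather than a log-binomial fit: this pairs
adjusted rates and adjusted RRs from a single model and avoids log-binomial
convergence failures.

**Multilevel ICC.** A random-intercept logistic model (hospital intercepts
u_h ~ N(0, σ²_u)) is fitted by direct maximization of the Gauss–Hermite
marginal likelihood (25 nodes; analytic gradients; L-BFGS-B with log σ
bounded in [1e−4, 20]). No installed Python package provides a frequentist
GLMM, so the quadrature fit is implemented here; its log-likelihood is
verified in the test suite against direct adaptive numerical integration.
The latent-scale ICC is σ²_u/(σ²_u + π²/3). The CI for σ²_u is Wald on the
log σ scale from the finite-difference observed information — chosen over a
bootstrap of GLMM refits, which costs two orders of magnitude more for the
same nominal coverage (verified empirically at σ_u = 0.5). Near σ = 0 the
log-scale interval degenerates and is reported as undefined.

## Benchmarks and shortfall

**ABC pared-mean.** Hospitals with fewer than `min_cases = 10` study cases
are removed (with an exact accounting of excluded patients). The remainder
are ranked by descending rate — ties broken toward larger hospitals (more
evidence), then lexicographic id, for deterministic output — and the
smallest prefix whose cumulative size reaches `fraction = 0.10` of the
eligible population is selected, so the selected share can exceed 10%. The
benchmark rate pools k/n over selected hospitals. The fraction denominator
is the post-exclusion (eligible) population, configurable. The adjusted
variant ranks on the indirectly standardized rates and reports their
n-weighted mean over the selected hospitals, with a percentile CI from the
per-hospital bootstrap draws.

**Criterion-based benchmark (CBB).** The case-mix-standardized rate at
factor level 1 (e.g. comprehensive cancer centres), from the marginal
standardization above, compared with the provincial rate.

**Shortfall** = (benchmark − actual)/benchmark × 100, on any consistent
scale; negative when the actual rate exceeds the benchmark; undefined at
benchmark ≤ 0.

**Selection bias of the pared-mean.** `abc_overestimation_experiment`
generates replicate cohorts under a configurable truth and recomputes all
benchmarks against the generator's true base rate. Under a pure-chance null
the pared-mean benchmark is biased upward (it conditions on observed rank,
so it selects favourable binomial noise — an order-statistics effect that
grows as hospital volumes shrink), while the CBB shortfall is centred on
zero. At the study's scale (72 hospitals, 2801 patients, heavy-tailed
volumes) the bias is roughly +0.10 on a true rate of 0.66, a manufactured
"shortfall" of ~13%.

## The synthetic cohort generator

The generator's defaults encode the study conditions: 72 hospitals, 2801
patients, pooled treatment probability 0.66, and the published covariate
marginals. Remaining structure is assumption, stated here:

- **Covariates are independent** across columns; only marginals are
  published. A correlation hook would be a config extension.
- **Hospital volumes** are unpublished; the "study-like" profile draws a
  lognormal(0, 1), splits it into a small stratum (25 hospitals, each 1–9
  cases, totalling 150 patients) and a large stratum (47 hospitals, ≥10
  cases, totalling 2651), and rescales each to integers — matching every
  published aggregate of the volume distribution.
- **Covariate effects** on the log-odds of treatment default to an age
  gradient (0, −0.2, −0.5, −1.3, −2.6 across the five age bands) and a
  Charlson gradient (0, −0.4, −0.8), reflecting the steep utilization
  decline with age and comorbidity reported for this population; no
  patient-level odds ratios are published, so the magnitudes are chosen
  once as plausible for a well-accepted adjuvant therapy and fixed. All
  other effects default to zero.
- **Length of stay** ~ 1 + NegBin(5, 5/12): integer days, mean 8, median 8.
- **Hospital attributes**: the largest hospitals are assigned the teaching
  (14/72), cancer-centre (13/72) and on-site-oncology (32/72) flags,
  mirroring the published counts and the observation that benchmark-ranked
  hospitals tend to be small community sites.
- **Hospital effects** u_h ~ N(0, `hospital_sd`) on the log-odds scale;
  `hospital_sd = 0` (the default) is the pure-chance null.

The intercept is calibrated by exact enumeration of the linear predictor's
distribution over the covariates with nonzero effects (they are
independent, so the rest integrate out) and monotone root-finding, making
the model-implied marginal rate equal `base_rate` to 1e−6. Randomness uses
one master seed with named substreams per stage (sizes, hospital effects,
one per covariate, outcomes), so identical configs are byte-identical on
disk and adding a covariate cannot perturb hospital sizes.

What the generator does *not* emulate: covariate correlation (real case mix
clusters — elderly patients at community sites), within-hospital surgeon
clustering, secular time trends, and hospital-attribute effects beyond the
random intercept. Tests passing on synthetic cohorts therefore validate
the statistical machinery under the stated structure, not the substantive
conclusions one would draw from real registry data.

## Numerical and testing notes

- Null coverage is tested with all covariate effects zero. With covariate
  heterogeneity each hospital count is Poisson-binomial, whose variance
  Σp_i(1−p_i) = n·p̄(1−p̄) − n·Var(p) is strictly below the binomial null's,
  so the common-p null slightly overstates chance variation and exact 95%
  coverage is not a theorem under the default gradients. In practice the
  overstatement is small relative to the interval width.
- Monte Carlo oracles: the expected CV is checked against brute-force
  enumeration of the full binomial outcome space on small configurations;
  the pared-mean against exhaustive prefix search; the GLMM likelihood
  against adaptive quadrature; bootstrap and Wald intervals against
  empirical coverage over replicate seeds.
- Problem sizes in the test suite (500 replicates × 200 iterations for CV
  coverage; 200 replicates for the selection-bias experiment; 150/100
  replicates for logistic/GLMM coverage) are chosen so Monte Carlo error is
  small against the tested bands while the full suite stays fast enough to
  run on every change.
- Degenerate inputs raise typed errors rather than NaNs: empty cohorts,
  constant outcomes or factors, all hospitals excluded, undefined CV
  (mean rate 0), zero expected rates, zero benchmarks, separation,
  singular designs, GLMM non-convergence.

## Known limitations

- The parametric bootstrap is a declared interpretation (coefficient
  redraw + offset-calibrated outcome redraw, percentile intervals); other
  defensible variants exist and would move interval widths somewhat.
- Adjusted pared-mean pooling (n-weighted mean of standardized rates) is
  likewise one of several defensible definitions.
- No shrinkage/empirical-Bayes hospital estimates, no funnel-plot control
  limits beyond the pooled-rate CI band, no overdispersion multipliers —
  natural extensions, out of scope here.
- SES-unknown handling (drop with warning) discards a handful of rows from
  adjusted analyses; own-category handling is available but makes the SES
  coefficient set non-comparable across cohorts with different unknown
  shares.
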