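# Methods

`bmdbatch` implements a standardized, fully automated benchmark-dose (BMD)
workflow for summary dose–response data: fit a prespecified suite of models by
maximum likelihood, compute the BMD at a standardized benchmark response
(BMR), compute its one-sided 95% lower bound (BMDL) by profile likelihood,
classify each fit with fixed adequacy rules, select a recommended model, and
— when a dataset cannot be modeled — retry after dropping the highest dose.
This note records the statistical model, the numerical choices, and the
design decisions taken where more than one reasonable option existed.

## Data model and likelihoods

Input data are group-level summaries: doses `d_i` (control at 0), group sizes
`n_i`, and either affected counts `y_i` (dichotomous and dichotomous-cancer
endpoints) or group means `m_i` and standard deviations `s_i` (continuous
endpoints). Datasets with fewer than three dose groups (including control)
are never fitted.

Dichotomous counts are binomial:
`LL = Σ_i [ y_i ln p(d_i) + (n_i − y_i) ln(1 − p(d_i)) ]`,
with probabilities clipped to `[1e−8, 1 − 1e−8]` inside the likelihood only
(reported predictions are never clipped). The binomial coefficient is a
parameter-free constant and is omitted consistently across models, so model
comparisons are unaffected.

Continuous summaries enter the normal likelihood through the sufficient
statistics:
`LL = Σ_i [ −(n_i/2) ln(2π σ_i²) − ((n_i−1)s_i² + n_i(m_i − μ(d_i))²)/(2σ_i²) ]`.
Full constants are retained so the fitted model's log-likelihood is directly
comparable with the saturated hierarchy used by the likelihood-ratio tests.
Two variance structures are fitted for every continuous mean model: constant
`σ²` and the power-of-the-mean model `σ_i² = α |μ(d_i)|^ρ` (ρ bounded to
[−18, 18], α > 0 via a log parameterization).

## Model suites

* Dichotomous: Gamma, Dichotomous Hill, Logistic, LogLogistic, Probit,
  LogProbit, Weibull, Multistage of degree `g − 1` (g dose groups; degree
  capped at 8 for conditioning).
* Continuous: Exponential 2–5, Hill, Power, Polynomial of degree `g − 1`,
  Linear — each under constant and modeled variance (16 candidates).
* Dichotomous-cancer: multistage-cancer at every degree from 1 to `g − 1`.

Power-type restrictions default on (Weibull/Gamma shape ≥ 1, power ≥ 1,
Hill coefficient ≥ 1, log-logistic/log-probit slope ≥ 1, exponential-3/5
power ≥ 1) and can be disabled per run; these are the usual risk-assessment
defaults, adopted here as the package default since the workflow is meant to
run unattended. Multistage coefficients are constrained non-negative, which
makes the fitted risk non-decreasing in dose.

The adversity direction of a continuous dataset is auto-detected from the
sign of the weighted least-squares slope of group means on dose and can be
overridden per dataset (`RunConfig.direction_override`). The BMR is a
magnitude, so the direction only orients the exponential-family forms and the
profile constraint.

## Maximum likelihood

Each model is optimized from a deterministic ladder of starting points:
moment-style anchors (transformed-scale regressions of observed response on
dose, pooled-variance and log-variance-regression anchors for the variance
block), each expanded with ×0.25 / ×1 / ×4 spreads on slope-type parameters.
Nelder–Mead within bounds is run from every start, the best result is
polished with L-BFGS-B and one refinement Nelder–Mead pass, and ties go to
the first solution found. There is no randomness anywhere in fitting, so
identical inputs give byte-identical outputs.

AIC is `−2 LL + 2k` with `k` the number of estimated parameters (variance
parameters included). Parameters that end on a bound are still counted; the
boundary-df corrections discussed in the small-sample literature are not
attempted.

## Fit diagnostics

Dichotomous fits get a Pearson chi-squared goodness-of-fit test
(`df = groups − parameters`; recorded as not computable when df < 1, with a
per-group variance floor of 1e−8 at fitted probabilities of 0 or 1).

Continuous fits are tested against the saturated hierarchy
A1 (group means, constant variance), A2 (group means, group variances),
A3 (group means, power variance model; `α` has a closed form given `ρ`, and
`ρ` is profiled by bounded scalar optimization), and R (single mean, constant
variance):

* Test 1, A2 vs R: is there any response at all;
* Test 2, A2 vs A1: variance homogeneity;
* Test 3, A2 vs A3: adequacy of the modeled variance;
* Test 4, saturated-means vs fitted model: adequacy of the mean model.

For Test 4 the saturated comparator carries the same variance structure as
the fit (A1 for constant-variance fits, A3 for modeled-variance fits), so a
mean model that passes through every group mean always gives a zero
statistic. A2 group variances use the MLE form `(n_i−1)s_i²/n_i`, floored at
1e−12 so a reported SD of exactly zero cannot produce an infinite
log-likelihood.

## BMD and BMDL

BMRs follow the standard reporting conventions: 10% extra risk
`(p(BMD) − p(0))/(1 − p(0)) = 0.10` for dichotomous and cancer endpoints, and
a change in the mean equal to 1 control SD for continuous endpoints. The
control SD is the **model-estimated** control SD — `σ̂` in constant mode,
`sqrt(α̂ |μ̂(0)|^ρ̂)` in modeled mode — not the observed control-group SD.
Added-risk and relative-deviation BMRs are deliberately not offered; the BMR
value itself is configurable.

BMD point estimates use closed forms wherever the family admits one (all
eight dichotomous forms, linear, power, Hill, multistage via polynomial
roots); the remaining cases bracket the unique crossing on a 600-point
log-spaced dose grid and polish with Brent's method (relative tolerance
1e−8). No root inside `(0, 100 × max dose]` means the BMD is recorded as not
estimable — a signal, never an exception.

The BMDL is the profile-likelihood one-sided 95% lower bound: the smallest
dose `D < BMD` at which the likelihood re-maximized under the constraint
`BMD = D` stays within `χ²₁(0.90)/2 = 1.35277` of the unconstrained maximum.
The constraint is imposed exactly by solving one slope-type parameter of each
family in closed form from the fixed BMD (e.g. `β₁` for multistage, `b` for
Weibull/Gamma/exponential, the intercept for log-dose forms, the response
span for Hill); the remaining parameters are re-optimized (bounded scalar
minimization in one dimension, Nelder–Mead with warm starts otherwise). The
profile deviance is root-found in log-dose with Brent's method; the search
floor is `max dose × 1e−8`, and a profile that never crosses the cutoff
above the floor yields a not-estimable BMDL (which downstream classification
treats as Questionable). The confidence level is configurable; level `L`
maps to the `χ²₁(2L − 1)` cutoff.

The 1-SD continuous BMR carries a known hybrid-risk interpretation: for a
normally distributed response, shifting the mean by one control SD makes the
fraction of the population beyond the control 2nd percentile
`Φ(1 − z₀.₉₈) − 0.02 ≈ 0.126`, i.e. roughly a 10% excess risk. The package
exposes this calculation (`one_sd_excess_fraction`) so the convention is
checkable rather than folklore.

## Decision logic

Every fit is classified:

* **Unusable** — optimizer failure, or neither BMD nor BMDL estimable.
* **Questionable** — goodness-of-fit p < 0.05; poorly modeled variance
  (constant-variance fit with Test 2 p < 0.10, or modeled-variance fit with
  Test 3 p < 0.10); BMDL above the highest dose; BMD/BMDL > 20; or BMDL not
  estimable.
* **Viable** — everything else, carrying non-fatal warnings: BMD or BMDL
  more than 3× below the lowest non-zero dose (low-dose extrapolation),
  BMD/BMDL > 5, marginal goodness of fit.

All thresholds live in `RuleConfig` (and the YAML config), so stricter or
looser rule sets can be recreated by configuration. A goodness-of-fit test
that is not computable (df < 1) does not disqualify a fit: absence of
evidence is not treated as failure, and the BMDL-quality rules still apply.

Selection among Viable fits: lowest AIC when the Viable BMDLs are
sufficiently close (no more than a 3-fold spread); otherwise the lowest BMDL.
Fits tying on the lowest AIC (absolute tolerance 1e−3 — floating-point
equality is not reproducible across platforms) with differing values have
their BMDs and BMDLs arithmetically averaged; geometric averaging would also
be defensible, but arithmetic is the plainer reading of "average" and the
choice only matters in the already-ambiguous tie case.

If no fit is Viable, the highest dose group is removed and the suite re-run,
repeatedly, as long as at least three dose groups (including control) remain.
Retries never run once a Viable fit exists. Across datasets, a chemical's
values are selected as (a) the lowest selected BMD — preferring
warning-free selections when any exist — with its own BMDL, and (b) the
lowest BMDL over all selections when it differs from (a)'s, regardless of
endpoint.

## Synthetic data

`SimDesign` declares a generating truth: a model spec with true parameters,
a dose pattern (geometric with ratio √10 by default, the typical bioassay
layout, with the top dose placed about 10× above the dose region of
interest; arithmetic and custom patterns available), group sizes, and the
noise law (binomial for dichotomous; normal with constant `σ` or power
variance `(α, ρ)` for continuous). Continuous replicates draw individual
responses and report the sample mean and sample SD, the way study tables are
produced, so reported SDs carry sampling noise just like real tables. The
same design and seed always reproduce the same dataset.

What the generator does **not** emulate: litter effects and other
extra-binomial clustering, historical-control information, time-course
structure, measurement rounding, and reporting artifacts (group sizes given
as ranges, missing SDs). Passing simulation-based tests therefore
demonstrates correctness of the statistical machinery under the stated
sampling models, not robustness to those real-data complications.

## Verification scenarios and problem sizes

The acceptance checks (tests and `scripts/acceptance.py`) use simulation
scales chosen to make each property sharply testable on a single CPU:

* **Profile-BMDL oracle**: 27 fits spanning every family on three fixture
  datasets are compared against a 200-point constrained-grid brute-force
  profile (full-vector SLSQP refits, independent of the package's
  reparameterized path), with the deviance at the returned BMDL checked
  against 2.70554 to 1e−3.
* **Coverage**: 2,000 binomial replicates from a degree-1 multistage truth
  (4 groups, n = 50, true BMD centered in the dose range); the fitted model
  matches the generating degree, so the check isolates the profile
  construction rather than model-selection effects. A replicate whose BMDL
  is not estimable counts as covered (a vacuous lower bound).
* **Recovery**: each family is fitted to data simulated from itself at
  n = 1,000/group on a five-point geometric-style design, with truths placed
  so the BMD is interior to the dose range and the curve steep enough for the
  BMD to be statistically identifiable at that sample size (median relative
  error under 5% over 50 replicates); shallow shape parameters near 1 leave
  the BMD genuinely under-determined even at this n, which is a property of
  the estimand, not the optimizer.
* **Design-factor sweep**: the viability-vs-dose-groups trend is reproduced
  with a deliberately information-poor truth — degree-1 multistage with the
  true BMD at 60% of the top dose, 10 animals/group, geometric spacing,
  3–6 groups, 500 replicates per cell — fitted with the multistage family
  (degree capped at 1). With this truth, 3-group designs often fail on BMDL
  quality (ratio > 20, BMDL above range, non-estimable), and viability rises
  steadily with added groups; the generator's general-purpose default (top
  dose ≈ 10 × BMD) is intentionally easier and shows no such gradient.
* **Null calibration**: Test 2 p-values under homoscedastic truth
  (4 groups, n = 100) and trend-test p-values under constant-proportion
  truth (4 levels, 200 per level) are checked for uniformity by
  Kolmogorov–Smirnov distance (< 0.05 at 2,000 replicates).

## Known limitations

* No nested-dichotomous, background-dose/response, repeated-response,
  concentration×time, or multi-tumor models; no individual-animal continuous
  data; no BMDU (upper bounds).
* No dosimetric adjustment: doses are modeled exactly as given.
* Boundary effects on AIC degrees of freedom are ignored (documented above).
* Group sizes must be single integers; reported ranges ("10–12") must be
  resolved by the user before input.
* The profile search assumes the constrained likelihood is unimodal along
  the profile path; pathological multimodal profiles would be detected only
  through the acceptance oracle, not at run time.
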