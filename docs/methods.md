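# Methods

## Survival machinery

Kaplan–Meier estimation uses the product-limit form with ties at one time
handled by a single factor `1 − d/n`; censored observations tied with an
event time remain in the risk set for that time (censoring is taken to
happen just after events at equal times — the standard convention, stated
explicitly because source descriptions of such analyses are usually
silent about it). An all-censored sample yields S ≡ 1 rather than an
error. `survival_rate_at` reads the step function at a horizon and flags
read-outs beyond the largest observed time instead of refusing them.

The log-rank test accumulates per-event-time observed and expected counts
and the hypergeometric variance

    V = Σ_t d_t (n₁t/Nt)(1 − n₁t/Nt)(Nt − d_t)/(Nt − 1),

with event times where everyone at risk belongs to one group contributing
zero to both numerator and variance (0/0 guarded). The "two-sided
p-value" is the upper χ² tail at df = groups − 1; the signed deviation
O₁ − E₁ is kept on the result for direction read-outs. For k > 2 groups
the quadratic form over the first k − 1 groups with the full covariance
matrix is used. The stratified variant sums O − E and V within strata
before forming the statistic (df = 1); a stratum with a single group
contributes nothing and is logged, not rejected — with one informative
stratum the test degrades gracefully to that stratum's evidence.

A permutation reference (`logrank_permutation_p`) enumerates all
`C(n, n₁)` group assignments exactly for small samples or samples them
uniformly. On small all-event samples the exact permutation p can differ
substantially from the χ²₁ tail (n = 4 with complete separation: 1/3 vs
0.09); the χ² approximation is an asymptotic one, and the permutation
reference is the honest small-sample standard against which the
machinery is validated.

## Cut-point scan

Candidates are the distinct observed marker values (not midpoints —
thresholds stay in original, clinically reportable units) whose
strict-greater dichotomization leaves both groups with at least
`ceil(min_group_frac · n)` members; the global maximum is always
excluded. "High" means strictly greater than the cut-point, so a
threshold chosen from the data leaves its defining patient in the low
group, matching the maximally-selected-statistics convention. The default
`min_group_frac = 0.10` is permissive enough to admit strongly unbalanced
splits (e.g. 52 vs 15 of 67) while excluding degenerate tails. Direction
is read from the sign of `O_high − E_high` (high group with fewer events
than expected ⇒ "direct", higher marker is protective) rather than from a
model fit: it is always defined when events exist and costs nothing.
Optimum = argmax χ², which at df = 1 is exactly argmin p; ties break to
the smallest candidate. The scan shares its O/E/V kernel with the
log-rank test, and tests assert element-wise equality against independent
log-rank calls.

Because the scan maximizes over candidates, its minimal p-value is
anti-conservative. The package's calibration study measures the naive
rule's type-I error at ≈ 0.4 for n = 67 cohorts at a nominal 0.05 —
the inflation the cross-validated test exists to correct.

## Cross-validated cut-point test

One uniformly random near-equal split (subset A takes the extra patient
when n is odd — arbitrary but fixed for reproducibility); each half is
scanned for its own minimum-p cut-point; each patient is labeled
above/below by the *other* half's cut-point; the pooled labeling is
tested by the log-rank test stratified by half. The split seed is a
required, recorded input. The procedure is a single split by definition;
`multi_split_pvalues` reports the p across many seeds as a sensitivity
extension only (the per-seed values are dependent and must not be
combined). A fold whose scan fails raises an error carrying the seed;
the calibration study resamples the split in that case rather than
discarding the replicate, which would bias the measured rejection rate.
Measured on 4000 null cohorts the test's rejection rate at α = 0.05 is
≈ 0.06 — essentially nominal, slightly liberal, against the naive rule's
≈ 0.4. Asymptotic corrections for maximally selected statistics
(Lausen–Schumacher type bounds) are deliberately out of scope; the
cross-validation is the procedure this package reproduces.

## Group comparisons

Pearson χ² without continuity correction and without an automatic Fisher
fallback, because that is the clinical-reporting convention the package
mirrors even with small cells (a Fisher option exists behind a flag; small
expected counts trigger a warning only). Mann–Whitney U uses midrank ties,
exact enumeration when `n₁·n₂ ≤ 400` and the data are tie-free, and the
continuity-corrected tie-adjusted normal approximation otherwise. Mean
summaries report the n − 1 standard deviation; the comparison p defaults
to Mann–Whitney (Welch's t available as `test="welch"`), since reports of
mean ± SD with a nonparametric p are common and the two can disagree.

## Cox regression

Continuous covariates pass through; categorical covariates are expanded
against explicit reference levels (the default clinical spec: sex ref
female, risk ref favorable, induction courses collapsed to {1, >1} ref 1,
consolidation ref HDAraC, marker group ref high so the reported HR is the
low group's). Incomplete rows are deleted listwise with a warned count;
unseen levels are errors. The partial likelihood is maximized by undamped
Newton iteration with Efron tie handling (smaller bias than Breslow;
Breslow is switchable for comparisons against references that use it),
converging when the relative log-likelihood change falls below 1e-9 or
100 iterations (flagged). Undamped Newton converges quadratically here,
leaving the estimate within ~1e-8 of the maximizer — damped
implementations can stop several 1e-6 short, which matters when
validating against brute-force likelihood maximization. Standard errors
come from the inverse observed information; CIs are Wald on the log scale
(`exp(β ± 1.96·se)`). No penalization is applied even at low
events-per-variable; the package reproduces the unpenalized clinical
model and emits an events-per-coefficient warning below 10. The score
test at β = 0 (`score_test_binary`) is computed by an independent loop
over events and equals the two-group log-rank χ² on untied data — the
cross-module consistency check.

## Synthetic cohorts

The generator emulates a 67-patient MRD-negative CR cohort: log-normal
pre-treatment platelet counts (median 43 ×10⁹/L, log-sd 0.85) and
recovery peaks (median 389, log-sd 0.42) joined by a Gaussian copula
(correlation ρ, default 0.2 — the true pre/peak dependence is unreported,
so ρ is a free parameter); the marker is always recomputed as peak − pre.
The log-sd values were chosen once so that ±2.5σ log-normal quantiles at
n = 67 bracket the reported ranges (3–282 and 122–984). Event times are
exponential with a change-point hazard: rate λ above the threshold
(default the 60th percentile of the drawn marker) and λ·θ below it, with
θ defaulting to 3 — the magnitude of the reported multivariate hazard
ratios — and θ = 1 giving the null. λ is calibrated in closed form to a
2-year event-free fraction of 0.563 in the high group. Censoring is
uniform administrative censoring on 5–90 months (the follow-up range).
Overall survival is built compositionally: a PFS event is a death
outright with probability 0.2, otherwise relapse followed by exponential
post-progression survival (median 12 months), censored administratively —
so OS ≥ PFS holds in synthetic data even though the data model only warns
on violations. Baseline covariates (sex 0.5, age uniform 3–69, risk
12/42/13 of 67, courses 43/21/3 of 67, consolidation 32/24/11 of 67) are
drawn independently of outcome, so baseline tables are homogeneous in
expectation. A linear-in-marker hazard mode exists for robustness
experiments.

What the generator does *not* emulate: covariate–outcome confounding,
non-proportional or time-varying hazards, informative censoring, and any
dependence of the marker on treatment course beyond the threshold effect.
Passing tests therefore demonstrate correctness of the procedures under
the change-point model they assume, not robustness of the clinical
conclusion to violations of it.

## Problem sizes and numerical choices

The validation suite uses 1000 null cohorts of n = 67 for the
selection-bias/calibration contrast, 200 replicates of n = 500 for
cut-point recovery (criterion: within 0.25 marker SDs of the truth), and
200 replicates of n = 1000 for Cox bias and CI coverage — sizes at which
the binomial/Monte-Carlo error of each check is small relative to its
acceptance band. All simulation randomness flows from explicit seeds
through `numpy.random.default_rng`; identical configuration and seed
reproduce every output byte-for-byte. Zero-variance event times, empty
candidate sets, all-censored samples, rank-deficient designs and
non-convergence are all handled explicitly (warning, typed error, or
flag) rather than left to downstream numerics.

## Known limitations

- The cross-validated p is split-dependent; the package records the seed
  and offers a sensitivity mode but, like the procedure it implements,
  does not aggregate over splits.
- The two-fold test is mildly liberal (≈ 0.06 at nominal 0.05 in the
  measured conditions); corrections for maximally selected statistics
  with analytic null distributions are out of scope.
- The k > 2-group log-rank path loops over event times in Python; it is
  intended for small clinical tables, not large-scale scanning (the
  two-group kernel used by the scan is vectorized).
- `survival_rate_at` extrapolates the last KM value beyond follow-up with
  a flag; downstream consumers must decide whether flagged values are
  reportable.
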