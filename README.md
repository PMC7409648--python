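# survcut

Optimal cut-point dichotomization of continuous survival biomarkers, with
honest (cross-validated) inference for the data-derived threshold.

## The problem

Clinical studies routinely turn a continuous biomarker into a two-group
prognostic factor by choosing the threshold that best separates survival
curves — e.g. the degree of platelet recovery
`ΔPLT = PLT_peak − PLT_pre` in AML patients reaching an MRD-negative
complete remission, dichotomized into "high" and "low" recovery groups.
The threshold is found by scanning every candidate value `c` and
maximizing the two-group log-rank statistic

    χ²(c) = (O₁(c) − E₁(c))² / V(c),

where `O₁`, `E₁`, `V` are the observed events, expected events and
hypergeometric variance of the high group (`marker > c`) summed over the
distinct event times. The maximum of χ²(c) over many candidate splits is a
*maximally selected* statistic: referring it to the ordinary χ²₁
distribution dramatically overstates significance (type-I error ≈ 0.4 at a
nominal 0.05 in cohorts of n = 67).

`survcut` implements both the scan and the correction used in practice: a
two-fold cross-validated cut-point test (Faraggi–Simon). The cohort is
randomly split into halves A and B; the optimal cut-point of A classifies
the patients of B and vice versa; the pooled above/below classification —
in which no patient's label depends on data that includes that patient —
is tested with a log-rank test stratified by half. The package also
provides the surrounding clinical workflow: Kaplan–Meier estimation and
survival rates at fixed horizons, (stratified) log-rank tests with exact
permutation references, baseline-table statistics (Pearson χ²,
Mann–Whitney U), Cox proportional-hazards regression with reference-level
encoding (Efron ties, Newton iteration), and a synthetic cohort generator
with a change-point hazard so every stage is testable without patient
data.

## Worked example

```bash
survcut simulate --seed 7 --out cohort.csv
# wrote 67 records to cohort.csv (threshold=348.2)
survcut analyze cohort.csv --outdir report --seed 7
# optimal cut-point (dplt): 434
# PFS: cross-validated chi2=6.270 p=0.0123
# OS: cross-validated chi2=0.171 p=0.6795
# report bundle written to report
```

The simulated 67-patient cohort has a true hazard ratio of 3 below the
348.2 threshold. The full-data scan selects 434 as the cut-point; the
cross-validated test confirms the progression-free-survival effect
honestly (p = 0.012) while the overall-survival effect, diluted by
post-progression noise at this sample size, is not significant
(p = 0.68). The report bundle contains the per-candidate χ² profile
(`cutpoint_profile_pfs.csv` — the tabular form of an X-tile pixel row),
Kaplan–Meier curve coordinates per group and endpoint, the baseline
comparison table, risk-factor (Cox) tables for both endpoints, and a
machine-readable `summary.json`.

The same machinery is available as a library:

```python
from survcut import Cohort, scan_cutpoints, cv_cutpoint_test

cohort = Cohort.read_csv("cohort.csv")
profile = scan_cutpoints(cohort.survival_sample("PFS"), cohort.marker("dplt"))
result = cv_cutpoint_test(cohort, endpoint="PFS", seed=7)
print(profile.optimal_value, result.p)
```

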