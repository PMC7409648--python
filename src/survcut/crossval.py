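"""Cross-validated significance test for a data-derived cut-point.

A data-driven threshold chosen to minimize the log-rank p-value cannot be
tested with that same p-value: the minimum over candidate splits is
anti-conservative (type-I error well above nominal).  The two-fold
cross-validation of Faraggi and Simon restores honesty:

1. randomly split the cohort into equal halves A and B;
2. find the optimal cut-point within A alone, and use it to label the
   patients of B as above / below; symmetrically label A with B's cut-point;
3. test the pooled above/below labeling with a log-rank test stratified by
   half.

No patient's label ever depends on a cut-point estimated from data that
includes that patient, so the stratified chi-square has its nominal null
distribution (df = 1) to a good approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .cohort import Cohort
from .cutpoint import scan_cutpoints
from .errors import StatisticalError, SubsetScanError, ValidationError
from .survival import SurvivalSample, stratified_logrank

__all__ = ["CrossValResult", "split_cohort", "cv_cutpoint_test", "multi_split_pvalues"]

ABOVE = "above"
BELOW = "below"


@dataclass
class CrossValResult:
    """Outcome of one two-fold cross-validated cut-point test."""

    seed: int
    split_assignment: np.ndarray  # per-patient "A" / "B", cohort order
    cutoff_A: float               # optimum found within subset A
    cutoff_B: float               # optimum found within subset B
    pooled_groups: np.ndarray     # per-patient "above" / "below"
    chi2: float
    p: float
    endpoint: str = "PFS"
    marker_field: str = "dplt"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subset": self.split_assignment, "pooled_group": self.pooled_groups}
        )

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "endpoint": self.endpoint,
            "marker": self.marker_field,
            "cutoff_A": self.cutoff_A,
            "cutoff_B": self.cutoff_B,
            "chi2": self.chi2,
            "p": self.p,
        }


def _split_indices(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random near-equal partition; subset A gets the extra
    member when n is odd (fixed for reproducibility)."""
    perm = rng.permutation(n)
    size_a = ceil(n / 2)
    return np.sort(perm[:size_a]), np.sort(perm[size_a:])


def split_cohort(cohort: Cohort, seed: int) -> tuple[list[str], list[str]]:
    """Randomly split a cohort into two near-equal halves.

    Reproducible given the seed and the cohort's record order.  Returns the
    two halves as patient-id lists.
    """
    n = len(cohort)
    if n < 4:
        raise ValidationError("need n >= 4 to cross-validate", field="cohort")
    rng = np.random.default_rng(seed)
    ia, ib = _split_indices(n, rng)
    ids = cohort.patient_ids
    return [ids[i] for i in ia], [ids[i] for i in ib]


def _cv_test_arrays(
    time: np.ndarray,
    event: np.ndarray,
    marker: np.ndarray,
    min_group_frac: float,
    seed: int,
) -> tuple[np.ndarray, float, float, np.ndarray, float, float]:
    """Array-level core of the cross-validated test (shared with the
    calibration study for speed)."""
    n = time.size
    if n < 4:
        raise ValidationError("need n >= 4 to cross-validate", field="sample")
    rng = np.random.default_rng(seed)
    ia, ib = _split_indices(n, rng)
    assignment = np.empty(n, dtype=object)
    assignment[ia] = "A"
    assignment[ib] = "B"

    cutoffs = {}
    for name, idx in (("A", ia), ("B", ib)):
        sub = SurvivalSample(time[idx], event[idx])
        if sub.event.sum() == 0:
            raise SubsetScanError("no events in subset", seed=seed, subset=name)
        try:
            prof = scan_cutpoints(sub, marker[idx], min_group_frac)
        except StatisticalError as exc:
            raise SubsetScanError(str(exc), seed=seed, subset=name) from exc
        cutoffs[name] = prof.optimal_value

    # honest assignment: each half is labeled by the *other* half's cutoff
    pooled = np.empty(n, dtype=object)
    pooled[ib] = np.where(marker[ib] > cutoffs["A"], ABOVE, BELOW)
    pooled[ia] = np.where(marker[ia] > cutoffs["B"], ABOVE, BELOW)

    test = stratified_logrank(
        SurvivalSample(time, event, group=pooled, stratum=assignment)
    )
    return assignment, cutoffs["A"], cutoffs["B"], pooled, test.chi2, test.p


def cv_cutpoint_test(
    cohort: Cohort,
    marker_field: str = "dplt",
    endpoint: str = "PFS",
    min_group_frac: float = 0.10,
    seed: int = 0,
) -> CrossValResult:
    """Two-fold cross-validated significance test of an optimal cut-point.

    A single random split per test (the procedure's definition); the seed is
    a required, recorded input.  A fold whose scan fails (no events or no
    admissible candidates) raises :class:`SubsetScanError` carrying the
    seed, so callers can resample or report.
    """
    sample = cohort.survival_sample(endpoint)
    marker = cohort.marker(marker_field)
    assignment, ca, cb, pooled, chi2, p = _cv_test_arrays(
        sample.time, sample.event, marker, min_group_frac, seed
    )
    return CrossValResult(
        seed=seed,
        split_assignment=assignment,
        cutoff_A=ca,
        cutoff_B=cb,
        pooled_groups=pooled,
        chi2=chi2,
        p=p,
        endpoint=endpoint,
        marker_field=marker_field,
    )


def multi_split_pvalues(
    cohort: Cohort,
    seeds,
    marker_field: str = "dplt",
    endpoint: str = "PFS",
    min_group_frac: float = 0.10,
) -> pd.DataFrame:
    """Sensitivity extension: the cross-validated p over many random splits.

    The single-split test is the procedure proper; this reports how the p
    varies with the split and is intended for sensitivity reporting only
    (the per-seed p-values are not independent and must not be combined
    into a single test).
    """
    rows = []
    for s in seeds:
        try:
            r = cv_cutpoint_test(cohort, marker_field, endpoint, min_group_frac, seed=int(s))
            rows.append(
                {"seed": int(s), "cutoff_A": r.cutoff_A, "cutoff_B": r.cutoff_B,
                 "chi2": r.chi2, "p": r.p, "error": ""}
            )
        except SubsetScanError as exc:
            rows.append(
                {"seed": int(s), "cutoff_A": np.nan, "cutoff_B": np.nan,
                 "chi2": np.nan, "p": np.nan, "error": str(exc)}
            )
    return pd.DataFrame(rows)
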