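"""Baseline-table statistics: Pearson chi-square for categorical features,
Mann-Whitney U for numeric ones, and mean +/- SD subgroup summaries.

These are the clinical-reporting workhorses for comparing patient subgroups
(e.g. high- vs low-marker, or single- vs multiple-course remission).  The
heavy lifting is delegated to scipy.stats; this module fixes the reporting
conventions: no continuity correction for the chi-square (a Fisher exact
option exists behind a flag), midrank ties and exact enumeration for small
Mann-Whitney samples, and n-1 standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ContingencyTable",
    "TwoSampleNumeric",
    "pearson_chi2",
    "mann_whitney_u",
    "two_sample_mean_summary",
    "MeanSummary",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list | None = None
    col_labels: list | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValidationError("table must be at least 2x2", field="counts")
        if np.any(self.counts < 0) or np.any(~np.isfinite(self.counts)):
            raise ValidationError("counts must be finite and >= 0", field="counts")

    @classmethod
    def from_labels(cls, a, b) -> "ContingencyTable":
        tab = pd.crosstab(pd.Series(a), pd.Series(b))
        return cls(tab.to_numpy(), list(tab.index), list(tab.columns))


@dataclass
class TwoSampleNumeric:
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size == 0 or self.y.size == 0:
            raise ValidationError("both samples must be non-empty", field="x")


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    p: float


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    method: str  # "exact" or "asymptotic"


def pearson_chi2(table: ContingencyTable, fisher: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity, no continuity correction.

    ``fisher=True`` switches a 2x2 table to Fisher's exact test (statistic
    reported as the odds ratio).  Small expected cells (< 5) trigger a
    warning but not a fallback — the chi-square is used as reported in the
    clinical convention this package mirrors.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("zero row or column marginal", field="counts")
    if fisher:
        if counts.shape != (2, 2):
            raise ValidationError("Fisher option requires a 2x2 table", field="counts")
        odds, p = stats.fisher_exact(counts)
        return ChiSquareResult(statistic=float(odds), df=1, p=float(p))
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell(s) < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


def mann_whitney_u(data: TwoSampleNumeric, exact_max_product: int = 400) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Exact enumeration of the null distribution when ``n1 * n2`` does not
    exceed ``exact_max_product`` and the pooled data has no ties; otherwise
    the normal approximation with tie-corrected variance and continuity
    correction.  The reported U is for the first sample.
    """
    x, y = data.x, data.y
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= exact_max_product and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return MannWhitneyResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)), method=method)


class MeanSummary(NamedTuple):
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    p: float
    test: str


def two_sample_mean_summary(data: TwoSampleNumeric, test: str = "mannwhitney") -> MeanSummary:
    """Per-group mean +/- sample SD with a two-sided comparison p-value.

    The default comparison is the Mann-Whitney U test; ``test="welch"``
    substitutes Welch's t-test for sensitivity reporting.  Sample standard
    deviations use the n-1 denominator (0 for a constant group of size 1 is
    undefined, hence the n >= 2 requirement).
    """
    x, y = data.x, data.y
    if x.size < 2 or y.size < 2:
        raise ValidationError("need n >= 2 per group for mean/SD summaries", field="x")
    if test == "mannwhitney":
        p = mann_whitney_u(data).p
    elif test == "welch":
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        raise ValidationError("test must be 'mannwhitney' or 'welch'", field="test")
    return MeanSummary(
        mean_x=float(np.mean(x)),
        sd_x=float(np.std(x, ddof=1)),
        mean_y=float(np.mean(y)),
        sd_y=float(np.std(y, ddof=1)),
        p=p,
        test=test,
    )
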