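"""Optimal cut-point search for a continuous survival biomarker.

Every distinct observed marker value is a candidate threshold; each
candidate dichotomizes the cohort (high = strictly greater), a two-group
log-rank test is run, and the candidate maximizing the chi-square (df = 1,
equivalently minimizing the p-value) is selected.  The per-candidate
direction records whether a high marker is associated with a better outcome
(fewer observed than expected events in the high group) or a worse one.

The maximum over many candidate splits is a maximally selected statistic:
its naive chi-square p-value is anti-conservative.  The honest inference
for a data-derived cut-point lives in :mod:`survcut.crossval`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoAdmissibleCutpointError, ValidationError
from .survival import SurvivalSample, _chi2_from_counts, _two_group_counts_sorted

__all__ = [
    "CutpointProfile",
    "candidate_cutpoints",
    "scan_cutpoints",
    "optimal_cutpoint",
    "marker_histogram",
]

DIRECT = "direct"      # higher marker -> better outcome (O_high < E_high)
INDIRECT = "indirect"  # higher marker -> worse outcome


@dataclass
class CutpointProfile:
    """Full scan of a marker: one log-rank test per candidate threshold."""

    marker_name: str
    candidates: np.ndarray   # strictly ascending marker values
    chi2: np.ndarray
    p: np.ndarray
    direction: np.ndarray    # "direct" / "indirect"
    n_high: np.ndarray
    n_low: np.ndarray
    optimal: int             # index of the selected candidate

    def __len__(self) -> int:
        return self.candidates.size

    @property
    def optimal_value(self) -> float:
        return float(self.candidates[self.optimal])

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: the data behind an X-tile-style pixel row."""
        return pd.DataFrame(
            {
                "candidate": self.candidates,
                "chi2": self.chi2,
                "p": self.p,
                "direction": self.direction,
                "n_high": self.n_high,
                "n_low": self.n_low,
            }
        )


def candidate_cutpoints(values, min_group_frac: float = 0.10) -> np.ndarray:
    """Admissible candidate thresholds for a marker vector.

    Candidates are the distinct observed values whose strict-greater
    dichotomization leaves both groups with at least
    ``ceil(min_group_frac * n)`` members.  The global maximum, whose high
    group is empty, is always excluded.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 observations", field="values")
    if not (0 <= min_group_frac < 0.5):
        raise ValidationError("min_group_frac must be in [0, 0.5)", field="min_group_frac")
    if np.any(~np.isfinite(arr)):
        raise ValidationError("marker values must be finite", field="values")
    n = arr.size
    min_size = max(ceil(min_group_frac * n), 1)
    distinct = np.unique(arr)
    srt = np.sort(arr)
    n_low = np.searchsorted(srt, distinct, side="right")
    n_high = n - n_low
    ok = (n_low >= min_size) & (n_high >= min_size)
    out = distinct[ok]
    if out.size == 0:
        raise NoAdmissibleCutpointError(
            f"no admissible candidate at min_group_frac={min_group_frac}; lower it"
        )
    return out


def scan_cutpoints(
    sample: SurvivalSample,
    marker,
    min_group_frac: float = 0.10,
    marker_name: str = "marker",
) -> CutpointProfile:
    """Log-rank chi-square profile of a marker over all admissible cut-points.

    At each candidate the cohort is dichotomized (high = strictly greater)
    and the two-group log-rank statistic computed.  Candidates whose split
    has no events at all get chi-square 0 and p 1.  The optimum is the
    argmax of chi-square; exact ties resolve to the smallest candidate.
    """
    m = np.asarray(marker, dtype=float)
    if m.shape != sample.time.shape:
        raise ValidationError("marker misaligned with sample", field="marker")
    cands = candidate_cutpoints(m, min_group_frac)
    if sample.event.sum() == 0:
        warnings.warn("no events in sample; profile is flat (chi2 = 0, p = 1)",
                      stacklevel=2)
    order = np.argsort(sample.time, kind="stable")
    ts = sample.time[order]
    es = sample.event[order] == 1
    ms = m[order]
    k = cands.size
    chi2 = np.zeros(k)
    direction = np.empty(k, dtype=object)
    n_high = np.zeros(k, dtype=int)
    n_low = np.zeros(k, dtype=int)
    for i, c in enumerate(cands):
        g = ms > c
        n_high[i] = int(g.sum())
        n_low[i] = ts.size - n_high[i]
        o, e, v = _two_group_counts_sorted(ts, es, g.astype(float))
        chi2[i] = _chi2_from_counts(o, e, v)
        direction[i] = DIRECT if o < e else INDIRECT
    p = np.where(chi2 > 0, stats.chi2.sf(chi2, 1), 1.0)
    optimal = int(np.argmax(chi2))  # first max = smallest candidate on ties
    return CutpointProfile(
        marker_name=marker_name,
        candidates=cands,
        chi2=chi2,
        p=p,
        direction=direction,
        n_high=n_high,
        n_low=n_low,
        optimal=optimal,
    )


def optimal_cutpoint(profile: CutpointProfile) -> float:
    """Selected threshold of a profile (argmax chi-square = argmin p)."""
    if len(profile) == 0:
        raise ValidationError("empty profile", field="profile")
    return profile.optimal_value


def marker_histogram(values, bins: int = 30) -> pd.DataFrame:
    """Marker distribution as a plain table (bin edges and counts)."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
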