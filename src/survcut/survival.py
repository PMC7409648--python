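"""Nonparametric survival machinery.

Kaplan-Meier product-limit estimation, the (stratified) log-rank test with
hypergeometric variance, survival-rate readout at fixed horizons, and an
exact/Monte-Carlo permutation reference for the two-group log-rank p-value.

Conventions (the field's standard ones):

* Censored observations tied with an event time stay in the risk set for
  that event — censoring is taken to happen just after events at equal
  times.
* The two-sided log-rank p-value is the upper tail of the chi-square
  distribution (df = groups - 1) at the statistic.  A signed variant of the
  two-group comparison (the sign of observed-minus-expected events in one
  group) is exposed for direction read-outs.
* Event times where everyone at risk is in one group contribute nothing to
  either the numerator or the variance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import StatisticalError, ValidationError

__all__ = [
    "SurvivalSample",
    "KmCurve",
    "LogrankResult",
    "SurvivalRate",
    "km_estimate",
    "survival_rate_at",
    "logrank_test",
    "stratified_logrank",
    "logrank_permutation_p",
    "two_group_counts",
]


@dataclass
class SurvivalSample:
    """Parallel vectors of follow-up time (months), event indicator and
    optional group / stratum labels."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None
    stratum: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.size == 0:
            raise ValidationError("at least one record required", field="time")
        if self.time.shape != self.event.shape:
            raise ValidationError("time and event lengths differ", field="event")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValidationError("times must be finite and >= 0", field="time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicators must be 0 or 1", field="event")
        for name in ("group", "stratum"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if lab.shape != self.time.shape:
                    raise ValidationError(f"{name} labels misaligned", field=name)
                setattr(self, name, lab)

    def __len__(self) -> int:
        return self.time.size

    def split_by_group(self) -> dict:
        if self.group is None:
            raise ValidationError("sample has no group labels", field="group")
        return {
            g: SurvivalSample(self.time[self.group == g], self.event[self.group == g])
            for g in np.unique(self.group)
        }


@dataclass
class KmCurve:
    """Kaplan-Meier step function.

    ``event_times`` are the ascending distinct times with at least one
    event; ``survival`` the product-limit values just after each;
    ``at_risk`` the number at risk just before each; ``n_events`` the events
    at each.  ``max_time`` is the largest observed (event or censoring)
    time, marking the end of support of the estimate.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int
    max_time: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


class SurvivalRate(NamedTuple):
    """S(t) at a horizon; ``beyond_followup`` flags extrapolation past the
    largest observed time."""

    value: float
    beyond_followup: bool


@dataclass
class LogrankResult:
    """(Possibly stratified) log-rank test.

    ``observed`` / ``expected`` are per-group event counts keyed by group
    label; ``o_minus_e`` keeps the signed deviation for direction read-outs.
    """

    chi2: float
    df: int
    p: float
    observed: dict
    expected: dict

    def o_minus_e(self, group) -> float:
        return self.observed[group] - self.expected[group]


def km_estimate(sample: SurvivalSample) -> KmCurve:
    """Product-limit estimator for a single-group sample.

    Ties at one time are handled by a single multiplicative factor
    ``1 - d/n``; tied censorings remain at risk for that factor.  An
    all-censored sample yields S identically 1 with no event times.
    """
    t, e = sample.time, sample.event
    n = t.size
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    ev = np.flatnonzero(es == 1)
    if ev.size == 0:
        return KmCurve(
            event_times=np.empty(0),
            survival=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            n=n,
            max_time=float(ts[-1]),
        )
    utimes, inv = np.unique(ts[ev], return_inverse=True)
    d = np.bincount(inv)
    at_risk = n - np.searchsorted(ts, utimes, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(
        event_times=utimes,
        survival=surv,
        at_risk=at_risk.astype(int),
        n_events=d.astype(int),
        n=n,
        max_time=float(ts[-1]),
    )


def survival_rate_at(curve: KmCurve, horizon: float) -> SurvivalRate:
    """Value of the KM step function at ``horizon`` months.

    Returns 1 before the first event.  When the horizon exceeds the largest
    observed time the last value is carried forward and flagged.
    """
    if horizon < 0:
        raise ValidationError("horizon must be >= 0", field="horizon")
    beyond = horizon > curve.max_time
    idx = np.searchsorted(curve.event_times, horizon, side="right") - 1
    value = 1.0 if idx < 0 else float(curve.survival[idx])
    return SurvivalRate(value=value, beyond_followup=beyond)


# -- log-rank ---------------------------------------------------------------


def two_group_counts(time, event, in_group) -> tuple[float, float, float]:
    """Summed O, E and hypergeometric variance for one group of a two-group
    log-rank comparison.

    ``in_group`` is a boolean (or 0/1) mask; returns ``(O, E, V)`` for the
    masked group, accumulated over the distinct event times.  This is the
    fast path shared by the unstratified test, the stratified test and the
    cut-point scan.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    g = np.asarray(in_group, dtype=float)
    order = np.argsort(t, kind="stable")
    return _two_group_counts_sorted(t[order], e[order] == 1, g[order])


def _two_group_counts_sorted(ts, es, gs) -> tuple[float, float, float]:
    """As :func:`two_group_counts` on pre-sorted arrays (``es`` boolean)."""
    n = ts.size
    ev = np.flatnonzero(es)
    if ev.size == 0:
        return 0.0, 0.0, 0.0
    ut, inv = np.unique(ts[ev], return_inverse=True)
    d = np.bincount(inv).astype(float)
    d1 = np.bincount(inv, weights=gs[ev])
    left = np.searchsorted(ts, ut, side="left")
    at_risk = (n - left).astype(float)
    cg = np.concatenate(([0.0], np.cumsum(gs)))
    n1 = cg[n] - cg[left]
    e1 = d * n1 / at_risk
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * (n1 / at_risk) * (1.0 - n1 / at_risk) * (at_risk - d) / (at_risk - 1.0)
    v = np.where(at_risk > 1.0, v, 0.0)
    return float(d1.sum()), float(e1.sum()), float(v.sum())


def _chi2_from_counts(o: float, e: float, v: float) -> float:
    if v <= 0.0:
        return 0.0
    return (o - e) ** 2 / v


def logrank_test(sample: SurvivalSample) -> LogrankResult:
    """Two-sided log-rank test across the sample's groups.

    For two groups the statistic is ``(O1 - E1)^2 / V`` with the
    hypergeometric variance summed over distinct event times; for k > 2
    groups the quadratic form over the first k-1 groups' observed-minus-
    expected vector with the full covariance matrix.  p is the upper
    chi-square tail with df = k - 1.
    """
    if sample.group is None:
        raise ValidationError("log-rank test requires group labels", field="group")
    labels, codes = np.unique(sample.group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise StatisticalError("log-rank test needs >= 2 non-empty groups")
    t, e = sample.time, sample.event
    total_events = int(e.sum())
    if total_events == 0:
        warnings.warn("no events in sample; log-rank chi2 = 0, p = 1", stacklevel=2)
        zeros = {lab: 0.0 for lab in labels}
        return LogrankResult(chi2=0.0, df=k - 1, p=1.0, observed=zeros, expected=dict(zeros))

    if k == 2:
        o1, e1, v = two_group_counts(t, e, codes == 0)
        chi2 = _chi2_from_counts(o1, e1, v)
        observed = {labels[0]: o1, labels[1]: total_events - o1}
        expected = {labels[0]: e1, labels[1]: total_events - e1}
        p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
        return LogrankResult(chi2=chi2, df=1, p=p, observed=observed, expected=expected)

    return _k_group_logrank(t, e, codes, labels)


def _k_group_logrank(t, e, codes, labels) -> LogrankResult:
    order = np.argsort(t, kind="stable")
    ts, es, cs = t[order], e[order] == 1, codes[order]
    n, k = ts.size, labels.size
    ev = np.flatnonzero(es)
    ut = np.unique(ts[ev])
    O = np.zeros(k)
    E = np.zeros(k)
    cov = np.zeros((k - 1, k - 1))
    onehot = np.eye(k)[cs]  # n x k membership
    cum = np.vstack([np.zeros(k), np.cumsum(onehot, axis=0)])
    for tj in ut:
        left = np.searchsorted(ts, tj, side="left")
        right = np.searchsorted(ts, tj, side="right")
        at_risk_by_group = cum[n] - cum[left]
        N = at_risk_by_group.sum()
        ev_here = es[left:right]
        d_by_group = onehot[left:right][ev_here].sum(axis=0)
        d = d_by_group.sum()
        if d == 0 or N <= 1:
            continue
        O += d_by_group
        E += d * at_risk_by_group / N
        frac = at_risk_by_group[: k - 1] / N
        block = np.diag(frac) - np.outer(frac, frac)
        cov += d * (N - d) / (N - 1) * block
    z = (O - E)[: k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(cov, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(cov) @ z)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return LogrankResult(
        chi2=chi2,
        df=k - 1,
        p=p,
        observed=dict(zip(labels.tolist(), O)),
        expected=dict(zip(labels.tolist(), E)),
    )


def stratified_logrank(sample: SurvivalSample) -> LogrankResult:
    """Stratified two-group log-rank test.

    O - E and variance contributions are accumulated within each stratum
    and summed across strata before forming ``(sum O-E)^2 / sum V``;
    df = 1.  A stratum containing only one group contributes nothing (this
    is logged as a warning, not an error).
    """
    if sample.group is None or sample.stratum is None:
        raise ValidationError("stratified test requires group and stratum labels", field="stratum")
    labels = np.unique(sample.group)
    if labels.size != 2:
        raise StatisticalError("stratified log-rank implemented for exactly 2 groups")
    o_tot = e_tot = v_tot = 0.0
    obs = {lab: 0.0 for lab in labels}
    exp = {lab: 0.0 for lab in labels}
    for s in np.unique(sample.stratum):
        m = sample.stratum == s
        if np.unique(sample.group[m]).size < 2:
            warnings.warn(f"stratum {s!r} contains a single group; contributes nothing", stacklevel=2)
            continue
        events_here = int(sample.event[m].sum())
        o1, e1, v = two_group_counts(sample.time[m], sample.event[m], sample.group[m] == labels[0])
        o_tot += o1
        e_tot += e1
        v_tot += v
        obs[labels[0]] += o1
        obs[labels[1]] += events_here - o1
        exp[labels[0]] += e1
        exp[labels[1]] += events_here - e1
    chi2 = _chi2_from_counts(o_tot, e_tot, v_tot)
    p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return LogrankResult(chi2=chi2, df=1, p=p, observed=obs, expected=exp)


def logrank_permutation_p(
    sample: SurvivalSample,
    n_permutations: int | None = None,
    rng: np.random.Generator | None = None,
    max_exact: int = 200_000,
) -> float:
    """Permutation p-value for the two-group log-rank statistic.

    Group labels are permuted over the fixed (time, event) records.  With
    ``n_permutations=None`` all ``C(n, n1)`` assignments are enumerated
    (refused above ``max_exact``); otherwise that many uniform random
    assignments are drawn.  The observed assignment counts itself in the
    Monte-Carlo tail, the standard unbiased convention.
    """
    if sample.group is None:
        raise ValidationError("permutation test requires group labels", field="group")
    labels = np.unique(sample.group)
    if labels.size != 2:
        raise StatisticalError("permutation reference implemented for 2 groups")
    t, e = sample.time, sample.event
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order] == 1
    g_obs = (sample.group == labels[0])[order]
    n, n1 = ts.size, int(g_obs.sum())
    chi2_obs = _chi2_from_counts(*_two_group_counts_sorted(ts, es, g_obs.astype(float)))

    def chi2_of(idx_tuple) -> float:
        g = np.zeros(n)
        g[list(idx_tuple)] = 1.0
        return _chi2_from_counts(*_two_group_counts_sorted(ts, es, g))

    tol = 1e-12
    if n_permutations is None:
        from math import comb

        if comb(n, n1) > max_exact:
            raise StatisticalError(
                f"exact enumeration over C({n},{n1}) assignments exceeds max_exact"
            )
        hits = total = 0
        for idx in itertools.combinations(range(n), n1):
            total += 1
            if chi2_of(idx) >= chi2_obs - tol:
                hits += 1
        return hits / total
    rng = np.random.default_rng() if rng is None else rng
    hits = 0
    for _ in range(n_permutations):
        idx = rng.choice(n, size=n1, replace=False)
        if chi2_of(idx) >= chi2_obs - tol:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
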