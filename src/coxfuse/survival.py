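"""Survival-analysis primitives.

The prognostic index (PI) produced by every model in this package is a
per-sample log hazard ratio eta; only its ordering matters downstream.
This module provides the Cox partial log-likelihood (the training
objective), Harrell's concordance index with the literal pair-counting
convention (ties in eta count as discordant), the Kaplan-Meier estimator,
the two-group log-rank test, and median-PI risk dichotomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalDataset",
    "RiskGroups",
    "cox_partial_log_likelihood",
    "c_index",
    "kaplan_meier",
    "log_rank_test",
    "dichotomize_by_median",
]


@dataclass
class SurvivalDataset:
    """Right-censored survival data with a per-sample feature matrix.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, aligned with the rows of ``X``.
    X : ndarray, shape (n, p)
        Numeric feature matrix; no missing values.
    T : ndarray, shape (n,)
        Positive time-to-event (or censoring time), e.g. days.
    d : ndarray, shape (n,)
        Event indicator: 1 if the event was observed, 0 if censored.
    """

    sample_ids: list
    X: np.ndarray
    T: np.ndarray
    d: np.ndarray
    feature_names: list = field(default=None)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.T = np.asarray(self.T, dtype=float).ravel()
        self.d = np.asarray(self.d).ravel()
        self.sample_ids = list(self.sample_ids)
        n = self.X.shape[0]
        if not (len(self.sample_ids) == len(self.T) == len(self.d) == n):
            raise ValueError(
                f"inconsistent lengths: ids={len(self.sample_ids)}, "
                f"X rows={n}, T={len(self.T)}, d={len(self.d)}"
            )
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if np.any(self.T <= 0):
            raise ValueError("all survival times must be positive")
        if not np.isin(self.d, (0, 1)).all():
            raise ValueError("event indicator must be coded 0/1")
        self.d = self.d.astype(int)
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.d.sum())

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset by integer index array; feature set is unchanged."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            [self.sample_ids[i] for i in idx],
            self.X[idx],
            self.T[idx],
            self.d[idx],
            feature_names=list(self.feature_names),
        )


@dataclass
class RiskGroups:
    """High/low risk labels from a prognostic-index split."""

    labels: np.ndarray  # array of "high"/"low"
    threshold: float

    @property
    def high_mask(self) -> np.ndarray:
        return self.labels == "high"

    @property
    def low_mask(self) -> np.ndarray:
        return self.labels == "low"


def _check_eta(eta, n):
    eta = np.asarray(eta, dtype=float).ravel()
    if len(eta) != n:
        raise ValueError(f"eta length {len(eta)} does not match n={n}")
    if not np.isfinite(eta).all():
        raise ValueError("eta contains non-finite values")
    return eta


def cox_partial_log_likelihood(eta, T, d) -> float:
    """Breslow partial log-likelihood of a risk score.

    Returns ``sum over events i of [eta_i - log sum_{j: T_j >= T_i} exp(eta_j)]``.
    Tied event times share the full risk-set denominator (Breslow).
    Invariant to adding a constant to eta.
    """
    T = np.asarray(T, dtype=float).ravel()
    d = np.asarray(d).ravel()
    n = len(T)
    if n == 0:
        raise ValueError("empty dataset: partial likelihood undefined")
    eta = _check_eta(eta, n)
    if d.sum() == 0:
        raise ValueError("no observed events: partial likelihood undefined")
    shift = eta.max()
    es = np.exp(eta - shift)
    order = np.argsort(T, kind="stable")
    Ts, ds, etas, ess = T[order], d[order], eta[order], es[order]
    # risk set of sample i (ascending order) is positions i..n-1, extended
    # left-to-right across ties so that T_j == T_i stays in the denominator
    rev_cum = np.cumsum(ess[::-1])[::-1]
    # ties: every member of a tie group gets the group's first (largest) cumsum
    first_of_group = np.ones(n, dtype=bool)
    first_of_group[1:] = Ts[1:] != Ts[:-1]
    group_start = np.maximum.accumulate(np.where(first_of_group, np.arange(n), 0))
    denom = rev_cum[group_start]
    ll = np.sum(ds * ((etas - shift) - np.log(denom)))
    return float(ll)


def c_index(eta, T, d) -> float:
    """Harrell's concordance index with the literal pair-counting rule.

    ``c = sum_{i!=j} 1{eta_i < eta_j} 1{T_i > T_j} d_j / sum_{i!=j} 1{T_i > T_j} d_j``

    A pair is usable when the sample with the shorter time had its event
    observed; tied times are not usable. Ties in eta count as discordant
    (the indicator is strict), so values may differ in the third decimal
    from packages that award 1/2 per tie.
    """
    T = np.asarray(T, dtype=float).ravel()
    d = np.asarray(d).ravel()
    n = len(T)
    if n < 2:
        raise ValueError("need at least two samples")
    eta = _check_eta(eta, n)
    longer = T[:, None] > T[None, :]        # 1{T_i > T_j}
    usable = longer & (d[None, :] == 1)     # weighted by d_j
    denom = usable.sum()
    if denom == 0:
        raise ValueError("no comparable pairs (check censoring and ties)")
    conc = (usable & (eta[:, None] < eta[None, :])).sum()
    return float(conc / denom)


def kaplan_meier(T, d, group_mask=None):
    """Product-limit survival estimate.

    Returns ``(times, S)`` where ``times`` are the sorted distinct observed
    times in the group and ``S`` the estimated survival just after each.
    """
    T = np.asarray(T, dtype=float).ravel()
    d = np.asarray(d).ravel()
    if group_mask is not None:
        group_mask = np.asarray(group_mask, dtype=bool)
        T, d = T[group_mask], d[group_mask]
    if len(T) == 0:
        raise ValueError("empty group: Kaplan-Meier undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(T, event_observed=d)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    S = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return times[keep], S[keep]


def log_rank_test(T, d, groups: RiskGroups):
    """Two-group log-rank test.

    Returns ``(chi2, p)``: the observed-minus-expected chi-square statistic
    on 1 df pooled over event times, and its asymptotic p-value.
    """
    T = np.asarray(T, dtype=float).ravel()
    d = np.asarray(d).ravel()
    hi, lo = groups.high_mask, groups.low_mask
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("both risk groups must be non-empty")
    res = _ll_logrank(T[hi], T[lo], event_observed_A=d[hi], event_observed_B=d[lo])
    return float(res.test_statistic), float(res.p_value)


def dichotomize_by_median(eta) -> RiskGroups:
    """Split samples into high/low risk at the median prognostic index.

    Samples with ``eta <= median`` are labelled low risk, ``eta > median``
    high risk. If ties at the median empty a group, falls back to a
    rank-based split placing the lowest ``floor(n/2)`` ranks in the low
    group.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    n = len(eta)
    if n < 2:
        raise ValueError("need at least two samples to stratify")
    if np.ptp(eta) == 0:
        raise ValueError("constant prognostic index: cannot stratify")
    thr = float(np.median(eta))
    labels = np.where(eta > thr, "high", "low")
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        order = np.argsort(eta, kind="stable")
        labels = np.empty(n, dtype=object)
        labels[order[: n // 2]] = "low"
        labels[order[n // 2:]] = "high"
        labels = labels.astype(str)
    return RiskGroups(labels=labels, threshold=thr)


def apply_threshold(eta, threshold: float) -> RiskGroups:
    """Label samples against an externally supplied PI threshold.

    Used to carry a training-split median onto held-out samples, so the
    test-set stratification never sees test labels.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    labels = np.where(eta > threshold, "high", "low")
    return RiskGroups(labels=labels, threshold=float(threshold))
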