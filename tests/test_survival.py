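"""Survival primitives against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coxfuse import (
    SurvivalDataset,
    c_index,
    cox_partial_log_likelihood,
    dichotomize_by_median,
    kaplan_meier,
    log_rank_test,
)
from coxfuse.survival import RiskGroups, apply_threshold

from conftest import random_survival


# ---------------------------------------------------------------- oracles

def pll_bruteforce(eta, T, d):
    """Breslow partial log-likelihood by explicit risk-set enumeration."""
    eta, T, d = map(np.asarray, (eta, T, d))
    ll = 0.0
    for i in range(len(T)):
        if d[i] == 1:
            risk = [j for j in range(len(T)) if T[j] >= T[i]]
            ll += eta[i] - np.log(sum(np.exp(eta[j]) for j in risk))
    return ll


def c_index_bruteforce(eta, T, d):
    """Pair-counting concordance by explicit double loop."""
    conc = comp = 0
    n = len(T)
    for i in range(n):
        for j in range(n):
            if i != j and T[i] > T[j] and d[j] == 1:
                comp += 1
                if eta[i] < eta[j]:
                    conc += 1
    return conc / comp


def km_bruteforce(T, d):
    """Product-limit estimate by explicit product over event times."""
    T, d = np.asarray(T, float), np.asarray(d)
    times = np.unique(T[d == 1])
    S, out = 1.0, []
    for t in times:
        at_risk = np.sum(T >= t)
        events = np.sum((T == t) & (d == 1))
        S *= 1.0 - events / at_risk
        out.append((t, S))
    return out


def logrank_bruteforce(T, d, in_a):
    """Textbook two-group log-rank: sum(O-E) with hypergeometric variance."""
    T, d, in_a = np.asarray(T, float), np.asarray(d), np.asarray(in_a, bool)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(T[d == 1]):
        n_tot = np.sum(T >= t)
        n_a = np.sum(T[in_a] >= t)
        d_tot = np.sum((T == t) & (d == 1))
        d_a = np.sum((T == t) & (d == 1) & in_a)
        e_a = d_tot * n_a / n_tot
        o_minus_e += d_a - e_a
        if n_tot > 1:
            var += (d_tot * (n_a / n_tot) * (1 - n_a / n_tot)
                    * (n_tot - d_tot) / (n_tot - 1))
    return o_minus_e ** 2 / var


# --------------------------------------------- Cox partial log-likelihood

def test_pll_two_sample_closed_form():
    assert cox_partial_log_likelihood([0, 0], [1, 2], [1, 1]) == pytest.approx(
        -np.log(2) + -np.log(1), abs=1e-12
    )


def test_pll_rejects_no_events():
    with pytest.raises(ValueError, match="events"):
        cox_partial_log_likelihood([1.0, 2.0], [1, 2], [0, 0])
    with pytest.raises(ValueError):
        cox_partial_log_likelihood([], [], [])


def test_pll_three_sample_matches_enumeration():
    eta, T, d = [1.0, -1.0, 0.5], [2, 5, 3], [1, 0, 1]
    assert cox_partial_log_likelihood(eta, T, d) == pytest.approx(
        pll_bruteforce(eta, T, d), abs=1e-12
    )


@pytest.mark.parametrize("seed", range(10))
def test_pll_matches_enumeration_random(seed):
    eta, T, d = random_survival(seed, n=30)
    if seed % 2:  # exercise tied event times (Breslow shared denominator)
        T = np.round(T)
        T[T == 0] = 1.0
    assert cox_partial_log_likelihood(eta, T, d) == pytest.approx(
        pll_bruteforce(eta, T, d), abs=1e-10
    )


@given(st.integers(0, 10_000), st.floats(-50, 50))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_pll_shift_invariance(seed, c):
    eta, T, d = random_survival(seed, n=20)
    assert cox_partial_log_likelihood(eta + c, T, d) == pytest.approx(
        cox_partial_log_likelihood(eta, T, d), abs=1e-8
    )


# ------------------------------------------------------- concordance index

def test_c_index_perfectly_concordant():
    # every higher-risk sample dies earlier -> perfect score
    assert c_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0
    assert c_index([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0


def test_c_index_random_scores_near_half():
    rng = np.random.default_rng(0)
    _, T, d = random_survival(5, n=100)
    vals = [c_index(rng.standard_normal(100), T, d) for _ in range(100)]
    assert 0.47 < np.mean(vals) < 0.53


@pytest.mark.parametrize("seed", range(20))
def test_c_index_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 100))
    eta, T, d = random_survival(seed + 1000, n=n,
                                censoring=float(rng.uniform(0, 0.8)))
    assert c_index(eta, T, d) == pytest.approx(
        c_index_bruteforce(eta, T, d), abs=1e-12
    )


def test_c_index_cross_checked_against_sksurv():
    # tie-free data: the strict rule and the 1/2-per-tie rule coincide,
    # so an independent library must agree exactly
    sksurv = pytest.importorskip("sksurv.metrics")
    eta, T, d = random_survival(12, n=80)
    expected = sksurv.concordance_index_censored(d.astype(bool), T, eta)[0]
    assert c_index(eta, T, d) == pytest.approx(expected, abs=1e-12)


def test_c_index_monotone_transform_invariance():
    eta, T, d = random_survival(3, n=40)
    base = c_index(eta, T, d)
    assert c_index(np.exp(eta), T, d) == base
    assert c_index(3 * eta - 7, T, d) == base


def test_c_index_complement_identity():
    # without ties, reversing the score mirrors the index around 1/2
    eta, T, d = random_survival(4, n=60)
    assert c_index(eta, T, d) + c_index(-eta, T, d) == pytest.approx(1.0)


def test_c_index_ties_in_eta_count_as_discordant():
    # the strict indicator awards nothing to tied predictions
    assert c_index([1.0, 1.0], [1, 2], [1, 1]) == 0.0


def test_c_index_no_comparable_pairs_raises():
    with pytest.raises(ValueError, match="comparable"):
        c_index([1, 2], [5, 5], [1, 1])  # tied times: no usable pair
    with pytest.raises(ValueError, match="comparable"):
        c_index([1, 2], [1, 2], [0, 1])  # the shorter time is censored


# ------------------------------------------------------------ Kaplan-Meier

def test_km_no_censoring_steps():
    t, s = kaplan_meier([1, 2, 3], [1, 1, 1])
    assert list(t) == [1, 2, 3]
    assert s == pytest.approx([2 / 3, 1 / 3, 0.0])


def test_km_all_censored_stays_at_one():
    _, s = kaplan_meier([1, 2, 3], [0, 0, 0])
    assert np.all(s == 1.0)


def test_km_mixed_case_matches_hand_product():
    T = [2, 3, 3, 5, 8, 9]
    d = [1, 1, 0, 1, 0, 1]
    t, s = kaplan_meier(T, d)
    expected = dict(km_bruteforce(T, d))
    for ti, si in zip(t, s):
        if ti in expected:
            assert si == pytest.approx(expected[ti], abs=1e-12)


def test_km_monotone_in_unit_interval():
    _, T, d = random_survival(9, n=80, censoring=0.4)
    _, s = kaplan_meier(T, d)
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((s >= 0) & (s <= 1))
    _, s0 = kaplan_meier(T, np.ones_like(d))
    assert s0[-1] == pytest.approx(0.0, abs=1e-12)


def test_km_empty_group_raises():
    with pytest.raises(ValueError, match="empty"):
        kaplan_meier([1, 2], [1, 1], [False, False])


# ---------------------------------------------------------------- log-rank

def _groups(mask):
    return RiskGroups(labels=np.where(mask, "high", "low"), threshold=0.0)


def test_logrank_identical_groups_is_null():
    T = np.r_[[1, 2, 3, 4, 5], [1, 2, 3, 4, 5.0]]
    d = np.ones(10, int)
    chi2, p = log_rank_test(T, d, _groups(np.r_[np.ones(5), np.zeros(5)] > 0))
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0, abs=1e-10)


def test_logrank_separation_strengthens_with_n():
    ps = []
    for n in (4, 10, 20):
        T = np.r_[np.arange(1, n + 1), np.arange(n + 1, 2 * n + 1)].astype(float)
        d = np.ones(2 * n, int)
        _, p = log_rank_test(T, d, _groups(np.r_[np.ones(n), np.zeros(n)] > 0))
        ps.append(p)
    assert ps[0] > ps[1] > ps[2]
    assert ps[2] < 0.01


def test_logrank_ten_sample_matches_oev_table():
    T = np.array([3, 5, 7, 2, 18, 4, 6, 9, 11, 30.0])
    d = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
    in_a = np.arange(10) < 5
    chi2, _ = log_rank_test(T, d, _groups(in_a))
    assert chi2 == pytest.approx(logrank_bruteforce(T, d, in_a), abs=1e-8)


def test_logrank_symmetric_under_label_swap():
    eta, T, d = random_survival(2, n=40)
    g = dichotomize_by_median(eta)
    swapped = RiskGroups(labels=np.where(g.labels == "high", "low", "high"),
                         threshold=g.threshold)
    assert log_rank_test(T, d, g)[0] == pytest.approx(
        log_rank_test(T, d, swapped)[0], abs=1e-12
    )


def test_logrank_empty_group_raises():
    with pytest.raises(ValueError, match="non-empty"):
        log_rank_test([1, 2], [1, 1], _groups(np.array([True, True])))


# --------------------------------------------------------- dichotomization

def test_median_split_even():
    g = dichotomize_by_median([1.0, 2.0, 3.0, 4.0])
    assert g.threshold == 2.5
    assert g.high_mask.sum() == 2 and g.low_mask.sum() == 2


def test_median_split_ties_at_threshold():
    # eta <= median -> low; here median is 1.5 so the split is clean 2/2
    g = dichotomize_by_median([1, 1, 2, 2])
    assert g.low_mask.sum() == 2 and g.high_mask.sum() == 2
    # unbalanced ties keep the <= rule (3 low / 1 high), no fallback
    g2 = dichotomize_by_median([1, 1, 1, 2])
    assert g2.low_mask.sum() == 3 and g2.high_mask.sum() == 1
    # ties at the maximum would empty "high": rank fallback restores 2/2
    g3 = dichotomize_by_median([1, 2, 2, 2])
    assert g3.low_mask.sum() == 2 and g3.high_mask.sum() == 2


def test_median_split_odd_n_boundary():
    g = dichotomize_by_median([10.0, 20.0, 30.0, 40.0, 50.0])
    # the median sample (30) sits on the low side of the <= rule
    assert g.labels[2] == "low"
    assert g.low_mask.sum() == 3 and g.high_mask.sum() == 2


def test_constant_eta_rejected():
    with pytest.raises(ValueError, match="constant"):
        dichotomize_by_median([1.0, 1.0, 1.0])


def test_apply_external_threshold():
    g = apply_threshold([0.1, 0.9], 0.5)
    assert list(g.labels) == ["low", "high"]


def test_dataset_invariants(tiny_dataset):
    with pytest.raises(ValueError, match="positive"):
        SurvivalDataset(["a"], [[1.0]], [0.0], [1])
    with pytest.raises(ValueError, match="0/1"):
        SurvivalDataset(["a", "b"], [[1.0], [2.0]], [1, 2], [1, 2])
    with pytest.raises(ValueError, match="duplicate"):
        SurvivalDataset(["a", "a"], [[1.0], [2.0]], [1, 2], [1, 1])
    sub = tiny_dataset.subset([0, 2])
    assert sub.sample_ids == ["a", "c"] and sub.n_events == 1
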