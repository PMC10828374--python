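"""Statistical-kernel tests: worked examples, enumeration oracles, and
null-calibration properties for the permutation engines."""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import metanoise as mn
from metanoise.stats import ols_slope

# ---------------------------------------------------------------- oracles


def mw_enumeration_p(x, y) -> float:
    """Two-sided Mann–Whitney p by full enumeration of label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    mu = len(x) * len(y) / 2.0
    obs = abs(u_stat(x, y) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def bh_stepup_bruteforce(p, q):
    """Textbook step-up: find the largest k with p_(k) <= q*k/m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_star = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


def fisher_enumeration_p(table) -> float:
    """Two-sided Fisher p by summing hypergeometric pmfs <= observed pmf."""
    (a, b), (c, d) = table
    r1, n, k = a + b, a + b + c + d, a + c
    lo, hi = max(0, k - (n - r1)), min(r1, k)
    pmf = {i: sps.hypergeom.pmf(i, n, r1, k) for i in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-9)))


# ------------------------------------------------------------ mann-whitney


def test_mann_whitney_worked_examples():
    r = mn.mann_whitney_two_tailed((1, 2, 3), (4, 5, 6))
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme
    # identical multisets: perfect symmetry
    r = mn.mann_whitney_two_tailed((5, 6, 7, 8), (5, 6, 7, 8))
    assert r.p_value == pytest.approx(1.0)
    # interleaved samples: exact branch equals the brute-force oracle
    x, y = (1, 3, 5, 7, 9), (2, 4, 6, 8, 10)
    assert mn.mann_whitney_two_tailed(x, y).p_value == pytest.approx(
        mw_enumeration_p(x, y)
    )


@settings(max_examples=60, deadline=None)
@given(st.data())
def test_mann_whitney_exact_matches_enumeration(data):
    """Exact branch agrees with full label enumeration for n1+n2 <= 10."""
    n1 = data.draw(st.integers(2, 5))
    n2 = data.draw(st.integers(2, 10 - n1))
    vals = data.draw(
        st.lists(
            st.floats(-50, 50, allow_nan=False),
            min_size=n1 + n2,
            max_size=n1 + n2,
            unique=True,
        )
    )
    x, y = vals[:n1], vals[n1:]
    assert mn.mann_whitney_two_tailed(x, y).p_value == pytest.approx(
        mw_enumeration_p(x, y)
    )


def test_mann_whitney_rejects_bad_input():
    with pytest.raises(ValueError):
        mn.mann_whitney_two_tailed([], [1, 2])
    with pytest.raises(ValueError):
        mn.mann_whitney_two_tailed([1, np.nan, 3], [1, 2, 4])


# --------------------------------------------------------------- spearman


def test_spearman_worked_examples():
    assert mn.spearman_correlation((1, 2, 3, 4), (10, 20, 30, 40)).statistic == pytest.approx(1.0)
    assert mn.spearman_correlation((1, 2, 3, 4), (40, 30, 20, 10)).statistic == pytest.approx(-1.0)
    # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 4
    r = mn.spearman_correlation((1, 2, 3, 4, 5), (1, 3, 2, 5, 4))
    assert r.statistic == pytest.approx(0.8)


def test_spearman_exact_p_small_n():
    """Exact permutation p at n=5 equals direct enumeration of pairings."""
    x, y = (1, 2, 3, 4, 5), (1, 3, 2, 5, 4)
    r = mn.spearman_correlation(x, y)
    rx = np.array(x, dtype=float)
    hits = total = 0
    for perm in permutations(range(5)):
        ry = np.array([y[i] for i in perm], dtype=float)
        total += 1
        if abs(np.corrcoef(rx, ry)[0, 1]) >= abs(r.statistic) - 1e-12:
            hits += 1
    assert r.p_value == pytest.approx(hits / total)
    assert r.method == "spearman-exact"


def test_spearman_t_approx_large_n():
    rng = np.random.default_rng(3)
    x = rng.normal(size=47)
    y = x + rng.normal(size=47)
    r = mn.spearman_correlation(x, y)
    ref = sps.spearmanr(x, y)
    assert r.statistic == pytest.approx(ref.statistic)
    assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)
    assert r.method == "spearman-t"


def test_spearman_constant_input_errors():
    with pytest.raises(ValueError, match="constant"):
        mn.spearman_correlation((1.0, 1.0, 1.0, 1.0), (1, 2, 3, 4))


# --------------------------------------------------------------------- BH


def test_bh_worked_example():
    rejected, q = mn.benjamini_hochberg([0.01, 0.02, 0.2], q_cutoff=0.1)
    assert rejected.tolist() == [True, True, False]


def test_bh_boundaries():
    rejected, _ = mn.benjamini_hochberg([1.0, 1.0, 1.0], 0.1)
    assert not rejected.any()
    rejected, _ = mn.benjamini_hochberg([0.0, 0.4, 0.9], 0.0)
    assert rejected.tolist() == [True, False, False]
    with pytest.raises(ValueError):
        mn.benjamini_hochberg([0.5, 1.5], 0.1)


@settings(max_examples=150, deadline=None)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
    st.sampled_from([0.05, 0.1, 0.2]),
)
def test_bh_matches_bruteforce_stepup(p, q):
    rejected, _ = mn.benjamini_hochberg(p, q)
    assert rejected.tolist() == bh_stepup_bruteforce(p, q).tolist()


# ------------------------------------------------------------ permutation


def test_permutation_median_diff_identical_groups():
    r = mn.permutation_median_diff([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_perm=200, seed=0)
    assert r.observed_stat == 0.0
    assert r.p_value == 1.0


def test_permutation_median_diff_extreme_split():
    """Monte-Carlo p approaches the exhaustive-enumeration value."""
    a, b = [1.0, 2.0, 3.0], [101.0, 102.0, 103.0]
    pooled = a + b
    obs = abs(np.median(a) - np.median(b))
    hits = total = 0
    for idx in combinations(range(6), 3):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(6) if i not in idx]
        total += 1
        hits += abs(np.median(xs) - np.median(ys)) >= obs
    exact = hits / total
    r = mn.permutation_median_diff(a, b, n_perm=4000, seed=0)
    assert r.p_value == pytest.approx(exact, abs=0.04)


def test_permutation_median_diff_deterministic():
    a, b = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
    r1 = mn.permutation_median_diff(a, b, n_perm=300, seed=42)
    r2 = mn.permutation_median_diff(a, b, n_perm=300, seed=42)
    assert r1.p_value == r2.p_value and r1.n_extreme == r2.n_extreme


def test_paired_slope_constant_series():
    a = {f"a{i}": [1.0] * 4 for i in range(4)}
    b = {f"b{i}": [1.0] * 4 for i in range(4)}
    r = mn.paired_permutation_slope_diff(a, b, window=[1, 2, 3, 4], n_perm=100, seed=0)
    assert r.observed_stat == 0.0
    assert r.p_value == 1.0


def test_paired_slope_detects_divergence():
    """Group A's across-hen spread widens over the window while group B's
    stays fixed, so the CV-slope difference is extreme vs within-hen nulls."""
    months = list(range(24, 31))
    a = {
        f"a{i}": [1.0 + (i - 2.5) * 0.12 * (t + 1) for t in range(7)] for i in range(6)
    }
    b = {f"b{i}": [1.0 + (i - 2.5) * 0.1 for _ in range(7)] for i in range(6)}
    r = mn.paired_permutation_slope_diff(a, b, window=months, n_perm=1000, seed=5)
    assert r.p_value <= 0.01


def test_paired_slope_window_too_short():
    a = {"a0": [1.0, 2.0]}
    with pytest.raises(ValueError, match="3 months"):
        mn.paired_permutation_slope_diff(a, a, window=[1, 2], n_perm=10, seed=0)


def test_ols_slope():
    assert ols_slope([1, 2, 3], [2, 4, 6]) == pytest.approx(2.0)


# ------------------------------------------------------------------ fisher


def test_fisher_worked_examples():
    # sterile/died contingency from a 32-hen cohort: 10/4 vs 1/17
    p = mn.fisher_exact_2x2([[10, 4], [1, 17]])
    assert round(p, 4) == 0.0001
    assert mn.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mn.fisher_exact_2x2([[1, -2], [3, 4]])


@settings(max_examples=100, deadline=None)
@given(st.tuples(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)))
def test_fisher_matches_enumeration(cells):
    a, b, c, d = cells
    if a + b + c + d == 0:
        return
    table = [[a, b], [c, d]]
    assert mn.fisher_exact_2x2(table) == pytest.approx(
        fisher_enumeration_p(table), rel=1e-6, abs=1e-12
    )


# ---------------------------------------------------------------- binomial


def test_binomial_survival_examples():
    # identical proportions -> maximal p
    assert mn.binomial_two_group_survival_test(5, 10, 5, 10) == pytest.approx(1.0)
    # closed-form tail: 0 deaths in 20 vs proportion 0.5 -> 2 * 0.5^20
    p = mn.binomial_two_group_survival_test(0, 20, 10, 20)
    assert p == pytest.approx(min(1.0, 2 * 0.5**20))


def test_binomial_survival_monotone_in_gap():
    """Widening the proportion gap at fixed n never increases p."""
    ps = [mn.binomial_two_group_survival_test(k, 40, 20, 40) for k in range(20, 3, -2)]
    assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))


def test_binomial_survival_conventions_differ():
    pa = mn.binomial_two_group_survival_test(11, 32, 4, 32, null="b")
    pb = mn.binomial_two_group_survival_test(11, 32, 4, 32, null="a")
    assert pa != pb  # the null-proportion choice is a real ambiguity
    with pytest.raises(ValueError):
        mn.binomial_two_group_survival_test(1, 0, 1, 10)
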