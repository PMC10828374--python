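"""Statistical kernel: rank tests, FDR, exact tests, and permutation engines.

Classical tests (Mann–Whitney, Spearman, Fisher, binomial) are delegated to
scipy/statsmodels with the conventions fixed here once, so every screen in
the package shares the same tie policy and sidedness.  The two permutation
engines — the hen-label median-difference test and the paired within-subject
slope test — are the heterogeneity statistics this package exists for and
are implemented directly.

Permutation p-values are reported as ``n_extreme / n_perm`` with "equal to
or bigger" counted as extreme; no +1 smoothing is applied, so p may be
exactly 0.  Increase ``n_perm`` when resolution below 1/n_perm matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PermutationResult",
    "mann_whitney_two_tailed",
    "spearman_correlation",
    "benjamini_hochberg",
    "permutation_median_diff",
    "paired_permutation_slope_diff",
    "fisher_exact_2x2",
    "binomial_two_group_survival_test",
    "ols_slope",
]

#: exact Mann–Whitney enumeration is used up to this combined sample size
#: (no ties); beyond it the normal approximation with tie and continuity
#: correction applies.
MW_EXACT_MAX_N = 14

#: Spearman p-values use exact permutation up to this n, the t-approximation
#: above it (so the pooled 47-hen screen always uses the t-approximation).
SPEARMAN_EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or correlation test."""

    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a label-permutation test.

    ``p_value`` is exactly ``n_extreme / n_perm`` (permutations at least as
    extreme as the observed statistic over the total attempted).
    """

    observed_stat: float
    n_extreme: int
    n_perm: int
    sided: str = "two-sided"
    null_stats: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.n_extreme <= self.n_perm):
            raise ValueError("n_extreme must lie in [0, n_perm]")

    @property
    def p_value(self) -> float:
        return self.n_extreme / self.n_perm


def _check_finite(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney_two_tailed(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Mann–Whitney U test.

    Uses the exact null distribution when ``len(x) + len(y) <= 14`` and the
    data are tie-free; otherwise the normal approximation with average-rank
    tie correction and continuity correction.  Returns U for the first
    sample.
    """
    x = _check_finite(x, "x")
    y = _check_finite(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) + len(y) <= MW_EXACT_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney-{method}",
    )


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates all n! pairings of the (possibly tied, average) ranks and
    counts |rho| >= |rho_obs| up to numerical tolerance.
    """
    from itertools import permutations

    n = len(rx)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    if denom == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    target = abs(rho_obs) * denom - 1e-12
    n_extreme = 0
    total = 0
    for perm in permutations(range(n)):
        total += 1
        if abs(float(cx @ cy[list(perm)])) >= target:
            n_extreme += 1
    return n_extreme / total


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is Pearson correlation on average ranks.  The p-value uses exact
    permutation of pairings for n <= 10 and the t-approximation above that.
    Constant input is an error (rho undefined), never a silent 0.
    """
    x = _check_finite(x, "x")
    y = _check_finite(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(rx, ry, rho)
        method = "spearman-exact"
    else:
        # t-approximation: t = rho * sqrt((n-2)/(1-rho^2))
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "spearman-t"
    return TestResult(statistic=rho, p_value=min(p, 1.0), method=method)


def benjamini_hochberg(
    p_values: Sequence[float], q_cutoff: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(rejected, q_values)`` where q-values are the monotone
    adjusted p-values (p·m/rank with a running minimum from the largest
    rank) and ``rejected[i]`` iff ``q_values[i] <= q_cutoff``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    _, q, _, _ = multipletests(p, alpha=q_cutoff, method="fdr_bh")
    rejected = q <= q_cutoff
    return rejected, q


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def permutation_median_diff(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    sided: str = "two-sided",
) -> PermutationResult:
    """Permutation test for a difference in group medians.

    The observed statistic is |median(a) − median(b)| (two-sided default;
    ``sided='greater'`` uses the signed difference median(a) − median(b)).
    Group labels are shuffled jointly and the statistic recomputed; a
    permutation counts as extreme when its statistic is >= the observed
    one.  p = n_extreme / n_perm.
    """
    a = _check_finite(a, "a")
    b = _check_finite(b, "b")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sided not in ("two-sided", "greater"):
        raise ValueError("sided must be 'two-sided' or 'greater'")
    rng = _resolve_rng(seed)
    pooled = np.concatenate([a, b])
    na = len(a)

    def stat(x1: np.ndarray, x2: np.ndarray) -> float:
        d = float(np.median(x1) - np.median(x2))
        return abs(d) if sided == "two-sided" else d

    observed = stat(a, b)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = stat(perm[:na], perm[na:])
    n_extreme = int(np.sum(null >= observed))
    return PermutationResult(observed, n_extreme, n_perm, sided, null_stats=null)


def ols_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """Ordinary least-squares slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("degenerate x: slope undefined")
    return float(xc @ (y - y.mean())) / denom


def _cv_trajectory(series: np.ndarray) -> np.ndarray:
    """Per-month coefficient of variation across subjects (rows=subjects)."""
    mean = series.mean(axis=0)
    if np.any(mean <= 0):
        raise ValueError("non-positive per-month mean: CV undefined")
    return series.std(axis=0, ddof=1) / mean


def paired_permutation_slope_diff(
    series_by_hen_a: Mapping[object, Sequence[float]],
    series_by_hen_b: Mapping[object, Sequence[float]],
    window: Sequence[float],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    trajectory: Callable[[np.ndarray], np.ndarray] | None = None,
    sided: str = "greater",
) -> PermutationResult:
    """Paired within-subject permutation test for a slope difference.

    Each hen contributes a time series over ``window`` (months).  The group
    "noise trajectory" is by default the per-month CV across hens; its OLS
    slope over the window summarises how heterogeneity drifts.  The test
    statistic is slope(A) − slope(B): order the groups so the alternative
    of interest is a larger slope in A.

    The null preserves each hen's value multiset: every hen's series is
    shuffled across months independently, the trajectories and slopes are
    recomputed, and a permutation counts as extreme when its statistic is
    >= the observed one (``sided='greater'``, the default — a fixed
    direction keeps the null rejection rate at nominal level) or when
    |statistic| >= |observed| (``sided='two-sided'``).
    """
    window = np.asarray(window, dtype=float)
    if len(window) < 3:
        raise ValueError("window must span at least 3 months")
    if not series_by_hen_a or not series_by_hen_b:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def stack(series_by_hen) -> np.ndarray:
        mat = np.asarray([np.asarray(v, dtype=float) for v in series_by_hen.values()])
        if mat.shape[1] != len(window):
            raise ValueError("every hen must cover the full window")
        if not np.all(np.isfinite(mat)):
            raise ValueError("non-finite series values")
        return mat

    if sided not in ("greater", "two-sided"):
        raise ValueError("sided must be 'greater' or 'two-sided'")
    mat_a = stack(series_by_hen_a)
    mat_b = stack(series_by_hen_b)
    traj = trajectory if trajectory is not None else _cv_trajectory
    rng = _resolve_rng(seed)

    def stat(ma: np.ndarray, mb: np.ndarray) -> float:
        d = ols_slope(window, traj(ma)) - ols_slope(window, traj(mb))
        return d if sided == "greater" else abs(d)

    observed = stat(mat_a, mat_b)
    m = len(window)
    null = np.empty(n_perm)
    pa, pb = mat_a.copy(), mat_b.copy()
    for i in range(n_perm):
        for mat, perm_mat in ((mat_a, pa), (mat_b, pb)):
            for h in range(mat.shape[0]):
                perm_mat[h] = mat[h, rng.permutation(m)]
        null[i] = stat(pa, pb)
    n_extreme = int(np.sum(null >= observed))
    return PermutationResult(observed, n_extreme, n_perm, sided, null_stats=null)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test p-value for a 2×2 contingency table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2×2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided").pvalue)


def binomial_two_group_survival_test(
    deaths_a: int, n_a: int, deaths_b: int, n_b: int, null: str = "b"
) -> float:
    """Two-sided binomial test comparing two groups' death proportions.

    With ``null='b'`` (default) group A's death count is tested against
    group B's observed proportion; ``null='a'`` swaps the roles.  Which
    group supplies the null proportion is a genuine reporting ambiguity in
    two-group binomial comparisons, hence the flag.
    """
    for deaths, n, name in ((deaths_a, n_a, "a"), (deaths_b, n_b, "b")):
        if n <= 0:
            raise ValueError(f"group {name} is empty")
        if not (0 <= deaths <= n):
            raise ValueError(f"group {name}: deaths must lie in [0, n]")
    if null == "b":
        return float(sps.binomtest(deaths_a, n_a, deaths_b / n_b).pvalue)
    if null == "a":
        return float(sps.binomtest(deaths_b, n_b, deaths_a / n_a).pvalue)
    raise ValueError("null must be 'a' or 'b'")
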