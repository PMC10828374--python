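"""Population-heterogeneity (noise) statistics.

The coefficient of variation σ/μ of a feature across the individuals of one
(group, age) cell is unitless, so the CVs of hundreds of features spanning
orders of magnitude can be pooled; the *median* of a cell's per-feature CVs
is the metabolic-noise scalar used to compare heterogeneity across ages and
treatment arms.  Reproduction noise applies the same σ/μ to individual
monthly laying efficiencies.  Significance everywhere comes from hen-label
permutation (between groups) or paired within-hen permutation (for slopes),
recomputing the full statistic per shuffle.

CVs are computed on raw positive intensities; z-scored input (mean ≈ 0) is
rejected rather than silently producing meaningless values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MetaboliteTable
from .stats import PermutationResult, paired_permutation_slope_diff, _resolve_rng

__all__ = [
    "NoiseSummary",
    "ReproductionNoise",
    "PanelSummary",
    "feature_cv",
    "metabolic_noise",
    "noise_trajectory",
    "reproduction_noise_trajectory",
    "reproduction_slope_test",
    "cytokine_panel_comparison",
]


@dataclass
class NoiseSummary:
    """Per-feature CVs of one (group, age) cell and their median."""

    group: str
    age_months: int
    cv_per_feature: pd.Series
    n_samples: int

    @property
    def median_cv(self) -> float:
        return float(self.cv_per_feature.median())


@dataclass(frozen=True)
class ReproductionNoise:
    group: str
    month: int
    cv: float
    n_hens: int


@dataclass
class PanelSummary:
    """Baseline-normalized cytokine panel with group medians.

    ``normalized`` is long-form (group, age_months, channel, value) where
    every channel's group average is divided by that group's baseline-age
    average, so baseline values are exactly 1.  ``group_median`` maps
    (group, age) -> median of the normalized channel values.
    """

    normalized: pd.DataFrame
    group_median: dict[tuple[str, int], float] = field(default_factory=dict)


def feature_cv(values) -> float:
    """Sample coefficient of variation: SD (n−1 denominator) over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 observations")
    if not (v > 0).all() or not v.mean() > 0:
        raise ValueError(
            "non-positive values: CVs must be computed on raw positive "
            "intensities, never on z-scored data"
        )
    return float(v.std(ddof=1) / v.mean())


def _cell_cvs(mat: np.ndarray) -> np.ndarray:
    means = mat.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("non-positive feature mean in cell")
    return mat.std(axis=1, ddof=1) / means


def metabolic_noise(table: MetaboliteTable, group: str, age: int) -> NoiseSummary:
    """Per-feature CVs across one cell's hens, summarised by their median."""
    sub = table.values_for(group, age)
    if sub.shape[1] < 2:
        raise ValueError(f"cell ({group}, {age}) has fewer than 2 samples")
    cvs = _cell_cvs(sub.to_numpy())
    return NoiseSummary(group, age, pd.Series(cvs, index=sub.index), sub.shape[1])


def noise_trajectory(
    table: MetaboliteTable,
    groups: tuple[str, str],
    ages: list[int],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[NoiseSummary], dict[int, PermutationResult]]:
    """Metabolic noise per (group, age) plus between-group permutation p.

    At every age where both groups have a populated cell, hen labels are
    permuted between the two cells and the full median-of-CV statistic is
    recomputed per shuffle; extreme means |median_cv difference| at least
    as large as observed.
    """
    rng = _resolve_rng(seed)
    summaries = []
    for g in groups:
        for a in ages:
            try:
                summaries.append(metabolic_noise(table, g, a))
            except ValueError:
                continue
    comparisons: dict[int, PermutationResult] = {}
    for a in ages:
        mats = []
        for g in groups:
            sub = table.values_for(g, a)
            if sub.shape[1] >= 2:
                mats.append(sub.to_numpy())
        if len(mats) != 2:
            continue
        na = mats[0].shape[1]
        pooled = np.concatenate(mats, axis=1)

        def stat(m: np.ndarray) -> float:
            return abs(
                float(np.median(_cell_cvs(m[:, :na])) - np.median(_cell_cvs(m[:, na:])))
            )

        observed = stat(pooled)
        n_extreme = 0
        for _ in range(n_perm):
            if stat(pooled[:, rng.permutation(pooled.shape[1])]) >= observed:
                n_extreme += 1
        comparisons[a] = PermutationResult(observed, n_extreme, n_perm, "two-sided")
    return summaries, comparisons


def reproduction_noise_trajectory(
    efficiencies: pd.DataFrame, group: str, months: list[int]
) -> list[ReproductionNoise]:
    """Per-month CV of individual monthly laying efficiencies for one group.

    ``efficiencies`` is the long-form table (hen_id, group, month,
    efficiency).  A month with fewer than 2 living hens, or with zero mean
    efficiency, is an error rather than a silent 0.
    """
    out = []
    sub = efficiencies[efficiencies["group"] == group]
    for m in months:
        vals = sub.loc[sub["month"] == m, "efficiency"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"month {m}: fewer than 2 living hens in {group}")
        mean = vals.mean()
        if not mean > 0:
            raise ValueError(f"month {m}: zero mean efficiency in {group}")
        out.append(ReproductionNoise(group, m, float(vals.std(ddof=1) / mean), len(vals)))
    return out


def reproduction_slope_test(
    efficiencies: pd.DataFrame,
    control_ids: list[str],
    molted_ids: list[str],
    window: list[int],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Compare reproduction-noise slopes over a post-molt window.

    Builds each hen's monthly efficiency series over ``window`` (every hen
    must cover the full window — the intended window is the post-molt
    period during which all hens are alive) and delegates to the paired
    within-hen slope permutation: the statistic is slope(control CV
    trajectory) − slope(molted CV trajectory).
    """
    def series(ids: list[str]) -> dict[str, np.ndarray]:
        out = {}
        for h in ids:
            sub = efficiencies[efficiencies["hen_id"] == h].set_index("month")
            missing = [m for m in window if m not in sub.index]
            if missing:
                raise ValueError(f"hen {h} missing months {missing} in window")
            out[h] = sub.loc[list(window), "efficiency"].to_numpy(dtype=float)
        return out

    return paired_permutation_slope_diff(
        series(control_ids), series(molted_ids), window, n_perm=n_perm, seed=seed
    )


def cytokine_panel_comparison(
    panel: pd.DataFrame,
    groups: tuple[str, str],
    ages: list[int],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[PanelSummary, dict[int, PermutationResult]]:
    """Baseline-normalized cytokine medians with per-age permutation p.

    Per group and channel, hen values are averaged at each age and divided
    by the same group's baseline-age (first of ``ages``) average, so every
    baseline channel is exactly 1; the representative measure per (group,
    age) is the median of the normalized channels.  At each later age the
    groups are compared by permuting hens (whole baseline+age trajectories)
    between groups and recomputing |median difference|.
    """
    baseline = ages[0]
    channels = sorted(panel["channel"].unique())
    rng = _resolve_rng(seed)

    def group_avg(sub: pd.DataFrame) -> np.ndarray:
        piv = sub.pivot_table(index="channel", values="value", aggfunc="mean")
        return piv.loc[channels, "value"].to_numpy(dtype=float)

    rows = []
    medians: dict[tuple[str, int], float] = {}
    base_avg: dict[str, np.ndarray] = {}
    for g in groups:
        sub0 = panel[(panel["group"] == g) & (panel["age_months"] == baseline)]
        if sub0.empty:
            raise ValueError(f"group {g}: no baseline ({baseline}) panel")
        avg0 = group_avg(sub0)
        if np.any(avg0 == 0):
            raise ValueError(f"group {g}: zero baseline channel average")
        base_avg[g] = avg0
        for a in ages:
            sub = panel[(panel["group"] == g) & (panel["age_months"] == a)]
            if sub.empty:
                continue
            norm = group_avg(sub) / avg0
            medians[(g, a)] = float(np.median(norm))
            rows.extend(
                {"group": g, "age_months": a, "channel": c, "value": v}
                for c, v in zip(channels, norm)
            )
    summary = PanelSummary(pd.DataFrame(rows), medians)

    comparisons: dict[int, PermutationResult] = {}
    ga, gb = groups
    for a in ages[1:]:
        # hens with complete panels at both the baseline and the tested age
        def hen_mats(g: str) -> tuple[list[str], np.ndarray, np.ndarray]:
            hens = sorted(
                set(panel.loc[(panel["group"] == g) & (panel["age_months"] == baseline), "hen_id"])
                & set(panel.loc[(panel["group"] == g) & (panel["age_months"] == a), "hen_id"])
            )
            def mat(age: int) -> np.ndarray:
                sub = panel[
                    (panel["group"] == g)
                    & (panel["age_months"] == age)
                    & (panel["hen_id"].isin(hens))
                ]
                piv = sub.pivot(index="hen_id", columns="channel", values="value")
                return piv.loc[hens, channels].to_numpy(dtype=float)
            return hens, mat(baseline), mat(a)

        hens_a, base_a, age_a = hen_mats(ga)
        hens_b, base_b, age_b = hen_mats(gb)
        if not hens_a or not hens_b:
            continue
        base_all = np.vstack([base_a, base_b])
        age_all = np.vstack([age_a, age_b])
        na = len(hens_a)

        def stat(order: np.ndarray) -> float:
            ia, ib = order[:na], order[na:]
            ma = np.median(age_all[ia].mean(axis=0) / base_all[ia].mean(axis=0))
            mb = np.median(age_all[ib].mean(axis=0) / base_all[ib].mean(axis=0))
            return abs(float(ma - mb))

        observed = stat(np.arange(len(hens_a) + len(hens_b)))
        n_extreme = 0
        for _ in range(n_perm):
            if stat(rng.permutation(len(hens_a) + len(hens_b))) >= observed:
                n_extreme += 1
        comparisons[a] = PermutationResult(observed, n_extreme, n_perm, "two-sided")
    return summary, comparisons
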