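"""Feature screening: aging biomarkers, reproduction biomarkers, and their
consistent intersection.

The aging screen tests every feature between each pair of the three control
timepoints (two-tailed Mann–Whitney), corrects each pair's full p-value
list by Benjamini–Hochberg at ``q_cutoff``, pools significant features
across pairs with an OR condition, and finally drops features whose three
group medians are not strictly monotone in age.  The reproduction screen
correlates each feature with sampling-month laying efficiency (Spearman)
across pooled control samples and applies the same FDR control.  Selection
is fully deterministic — no RNG anywhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CONTROL, MOLTED, MetaboliteTable
from .stats import MW_EXACT_MAX_N, benjamini_hochberg, mann_whitney_two_tailed, spearman_correlation

__all__ = [
    "BiomarkerRecord",
    "BiomarkerSet",
    "select_aging_biomarkers",
    "select_laying_biomarkers",
    "common_markers",
    "recovery_metrics",
]

INCREASING = "increasing"
DECREASING = "decreasing"


@dataclass
class BiomarkerRecord:
    feature_id: str
    p_by_pair: dict[str, float] = field(default_factory=dict)
    q_by_pair: dict[str, float] = field(default_factory=dict)
    significant_pairs: list[str] = field(default_factory=list)
    medians: dict[int, float] = field(default_factory=dict)
    age_direction: str | None = None
    rho: float | None = None
    rho_p: float | None = None
    rho_q: float | None = None


@dataclass
class BiomarkerSet:
    """A selected feature list with its selection parameters."""

    kind: str  # aging | laying | common
    records: list[BiomarkerRecord]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.feature_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("records must be unique by feature_id")

    @property
    def feature_ids(self) -> list[str]:
        return [r.feature_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"kind": self.kind, "params": self.params,
                 "records": [asdict(r) for r in self.records]},
                indent=1, default=str,
            )
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for r in self.records:
            row: dict = {"feature_id": r.feature_id, "age_direction": r.age_direction,
                         "rho": r.rho, "rho_q": r.rho_q,
                         "significant_pairs": ";".join(r.significant_pairs)}
            for pair, p in r.p_by_pair.items():
                row[f"p_{pair}"] = p
                row[f"q_{pair}"] = r.q_by_pair.get(pair)
            for age, m in r.medians.items():
                row[f"median_t{age}"] = m
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _pairwise_mw_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-feature two-tailed Mann–Whitney p-values (rows = features)."""
    n = a.shape[1] + b.shape[1]
    if n > MW_EXACT_MAX_N:
        res = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    return np.array(
        [mann_whitney_two_tailed(a[i], b[i]).p_value for i in range(a.shape[0])]
    )


def select_aging_biomarkers(
    table: MetaboliteTable,
    q_cutoff: float = 0.1,
    ages: tuple[int, int, int] | None = None,
) -> BiomarkerSet:
    """Aging-biomarker screen over three control timepoints.

    ``table`` must contain control samples at exactly three ages (pass
    ``ages`` to restrict); each cell needs at least 3 samples.  Features
    significant (BH q ≤ ``q_cutoff``, corrected within each pair's full
    p-value list) in at least one pair and with strictly monotone group
    medians across the three ages are returned with their direction.
    """
    control = table.subset(group=CONTROL, ages=list(ages) if ages else None)
    present = sorted({s.age_months for s in control.samples})
    if ages is None:
        if len(present) != 3:
            raise ValueError(
                f"expected exactly three control timepoints, found {present}"
            )
        ages = tuple(present)
    elif sorted(ages) != present:
        raise ValueError(f"requested ages {sorted(ages)} but table has {present}")
    a1, a2, a3 = sorted(ages)
    cells = {a: control.values_for(CONTROL, a).to_numpy() for a in (a1, a2, a3)}
    for a, mat in cells.items():
        if mat.shape[1] < 3:
            raise ValueError(f"age {a}: fewer than 3 control samples")

    feature_ids = control.feature_ids
    pairs = [(a1, a2), (a1, a3), (a2, a3)]
    pair_names = [f"t{x}-t{y}" for x, y in pairs]
    p_mat = np.vstack([_pairwise_mw_pvalues(cells[x], cells[y]) for x, y in pairs])
    q_mat = np.empty_like(p_mat)
    rej = np.empty_like(p_mat, dtype=bool)
    for k in range(3):
        rej[k], q_mat[k] = benjamini_hochberg(p_mat[k], q_cutoff)
    pooled = rej.any(axis=0)  # OR condition across pairs

    medians = {a: np.median(cells[a], axis=1) for a in (a1, a2, a3)}
    increasing = (medians[a1] < medians[a2]) & (medians[a2] < medians[a3])
    decreasing = (medians[a1] > medians[a2]) & (medians[a2] > medians[a3])
    keep = pooled & (increasing | decreasing)

    records = []
    for i in np.flatnonzero(keep):
        records.append(
            BiomarkerRecord(
                feature_id=feature_ids[i],
                p_by_pair={n: float(p_mat[k, i]) for k, n in enumerate(pair_names)},
                q_by_pair={n: float(q_mat[k, i]) for k, n in enumerate(pair_names)},
                significant_pairs=[n for k, n in enumerate(pair_names) if rej[k, i]],
                medians={a: float(medians[a][i]) for a in (a1, a2, a3)},
                age_direction=INCREASING if increasing[i] else DECREASING,
            )
        )
    return BiomarkerSet("aging", records, {"q_cutoff": q_cutoff, "ages": [a1, a2, a3]})


def select_laying_biomarkers(
    table: MetaboliteTable,
    efficiencies: pd.DataFrame,
    q_cutoff: float = 0.1,
) -> BiomarkerSet:
    """Reproduction-biomarker screen on pooled control samples.

    Each sample is paired with its own hen's laying efficiency for the
    sampling month (long-form ``efficiencies`` with hen_id/month/
    efficiency); per-feature Spearman rho and p across all pooled control
    samples are FDR-corrected over the full feature list.
    """
    control = table.subset(group=CONTROL)
    if not control.samples:
        raise ValueError("no control samples")
    eff_of = {
        (str(r.hen_id), int(r.month)): float(r.efficiency)
        for r in efficiencies.itertuples()
    }
    eff = []
    for s in control.samples:
        key = (s.hen_id, s.sampling_month)
        if key not in eff_of:
            raise ValueError(f"no efficiency for hen {s.hen_id} month {s.sampling_month}")
        eff.append(eff_of[key])
    eff = np.asarray(eff)

    mat = control.intensities.to_numpy()
    feature_ids = control.feature_ids
    results = [spearman_correlation(mat[i], eff) for i in range(mat.shape[0])]
    p = np.array([r.p_value for r in results])
    rej, q = benjamini_hochberg(p, q_cutoff)
    records = [
        BiomarkerRecord(
            feature_id=feature_ids[i],
            rho=float(results[i].statistic),
            rho_p=float(p[i]),
            rho_q=float(q[i]),
        )
        for i in np.flatnonzero(rej)
    ]
    return BiomarkerSet(
        "laying", records, {"q_cutoff": q_cutoff, "n_samples": len(eff)}
    )


def common_markers(
    aging: BiomarkerSet,
    laying: BiomarkerSet,
    table: MetaboliteTable,
    require_sign_consistency: bool = True,
    require_molted_between: bool = True,
) -> BiomarkerSet:
    """Features in both screens, consistent with molt-slowed aging.

    The intersection is filtered by two individually toggleable
    consistency conditions: (a) the efficiency correlation opposes the age
    trend — sign(rho) = −sign(age slope), so higher efficiency looks
    younger; (b) the molted t33 group median lies between the control t21
    and t33 medians — molted expression at the endpoint is younger than
    its age-matched control.
    """
    if not set(aging.feature_ids) <= set(table.feature_ids) or not set(
        laying.feature_ids
    ) <= set(table.feature_ids):
        raise ValueError("biomarker sets and table use different feature universes")
    laying_by_id = {r.feature_id: r for r in laying.records}
    a1, _, a3 = aging.params["ages"]
    ctrl_first = table.values_for(CONTROL, a1)
    ctrl_last = table.values_for(CONTROL, a3)
    try:
        molt_last = table.values_for(MOLTED, a3)
    except Exception:
        molt_last = pd.DataFrame(index=table.intensities.index)
    if require_molted_between and molt_last.shape[1] == 0:
        raise ValueError("no molted samples at the final timepoint")

    records = []
    for rec in aging.records:
        lay = laying_by_id.get(rec.feature_id)
        if lay is None:
            continue
        if require_sign_consistency:
            age_sign = 1 if rec.age_direction == INCREASING else -1
            if np.sign(lay.rho) != -age_sign:
                continue
        if require_molted_between:
            m_c1 = float(ctrl_first.loc[rec.feature_id].median())
            m_c3 = float(ctrl_last.loc[rec.feature_id].median())
            m_m3 = float(molt_last.loc[rec.feature_id].median())
            lo, hi = min(m_c1, m_c3), max(m_c1, m_c3)
            if not (lo <= m_m3 <= hi):
                continue
        merged = BiomarkerRecord(**{**asdict(rec)})
        merged.rho, merged.rho_p, merged.rho_q = lay.rho, lay.rho_p, lay.rho_q
        records.append(merged)
    return BiomarkerSet(
        "common",
        records,
        {
            "sign_consistency": require_sign_consistency,
            "molted_between": require_molted_between,
        },
    )


def recovery_metrics(selected_ids, true_ids) -> dict[str, float]:
    """Sensitivity and precision of a selection against planted truth."""
    selected, true = set(selected_ids), set(true_ids)
    tp = len(selected & true)
    return {
        "n_selected": len(selected),
        "n_true": len(true),
        "sensitivity": tp / len(true) if true else float("nan"),
        "precision": tp / len(selected) if selected else float("nan"),
    }
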