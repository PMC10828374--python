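"""Metabolic-age and laying-efficiency prediction.

All models consume per-feature z-scores whose normalization constants come
from a designated *reference* sample set (the training samples), so
held-out and transfer samples are always standardized by train-time
statistics — the only leakage-safe convention.  The metabolic-age axis is
PC1 of the control samples' aging-biomarker z-scores, oriented so older
control medians sit at larger coordinates; quantitative age and efficiency
predictions use a random-forest regressor (500 trees, unlimited depth,
1/3-feature subsampling, seeded), optionally behind a LASSO feature screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV

from .cohort import CONTROL, MOLTED, MetaboliteTable
from .stats import PermutationResult, _resolve_rng

__all__ = [
    "NormalizedTable",
    "AgeAxisProjection",
    "AgePredictionResult",
    "PredictionEvaluation",
    "zscore_normalize",
    "pca_age_axis",
    "median_axis_aging",
    "aging_contrast_permutation",
    "train_age_regressor",
    "predict_ages",
    "loo_predict_efficiency",
    "predict_efficiency_transfer",
]

#: frozen forest hyperparameters (seeded per call)
RF_N_TREES = 500
RF_MAX_FEATURES = 1.0 / 3.0


@dataclass
class NormalizedTable:
    """Per-feature z-scores with the constants that produced them."""

    zscores: pd.DataFrame  # features × samples
    mean: pd.Series
    sd: pd.Series
    reference_samples: list[str]

    def transform(self, intensities: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored train-time constants to new samples."""
        sub = intensities.loc[self.mean.index]
        return sub.sub(self.mean, axis=0).div(self.sd, axis=0)


@dataclass
class AgeAxisProjection:
    """Sample coordinates on the first two control-derived PCs."""

    coords: pd.DataFrame  # index sample_id, columns PC1, PC2
    explained_variance: tuple[float, float]
    orientation_flipped: bool

    def __post_init__(self) -> None:
        ev1, ev2 = self.explained_variance
        if not (0 <= ev2 <= ev1 <= 1):
            raise ValueError("explained-variance fractions must satisfy 1 >= PC1 >= PC2 >= 0")


@dataclass
class AgePredictionResult:
    """Per-sample predicted ages plus cohort medians per (group, age)."""

    predictions: pd.DataFrame  # sample_id, hen_id, group, true_age, predicted_age
    group_medians: dict[tuple[str, int], float] = field(default_factory=dict)


@dataclass
class PredictionEvaluation:
    """Predicted-vs-true evaluation for efficiency models."""

    predictions: pd.DataFrame  # sample_id, true, predicted
    pearson_r: float
    p_value: float
    capture_rate: float  # of true > threshold samples, fraction predicted > threshold
    threshold: float = 0.5


def zscore_normalize(
    table: MetaboliteTable,
    reference: list[str] | None = None,
    features: list[str] | None = None,
) -> NormalizedTable:
    """Standardize each feature to mean 0 / SD 1 over the reference samples.

    ``reference`` (sample ids) defaults to all samples; all columns are
    transformed with the reference-derived constants.  A zero-variance
    feature over the reference is an error naming the feature.
    """
    mat = table.intensities
    if features is not None:
        mat = mat.loc[features]
    ref_ids = reference if reference is not None else list(mat.columns)
    missing = set(ref_ids) - set(mat.columns)
    if missing:
        raise ValueError(f"reference samples not in table: {sorted(missing)}")
    ref = mat[ref_ids]
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    dead = sd[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance feature over reference: {dead.index[0]}")
    z = mat.sub(mean, axis=0).div(sd, axis=0)
    return NormalizedTable(z, mean, sd, list(ref_ids))


def pca_age_axis(
    norm: NormalizedTable,
    sample_meta: pd.DataFrame,
    control_ages: tuple[int, int] | None = None,
) -> AgeAxisProjection:
    """PC1/PC2 of the control sample cloud, with molted samples projected on.

    The axes are fitted on the normalization-reference (control) samples
    only; every sample in ``norm`` is then projected.  PC1's sign is fixed
    deterministically so the control median coordinate at the oldest age
    exceeds the one at the youngest (older = larger; the axis orientation
    is a convention).
    """
    ref_ids = norm.reference_samples
    if len(ref_ids) < 3:
        raise ValueError("need at least 3 reference samples for PCA")
    X_ref = norm.zscores[ref_ids].to_numpy().T
    if np.allclose(X_ref, X_ref[0]):
        raise ValueError("degenerate (rank-0) reference matrix")
    n_comp = min(2, X_ref.shape[1], len(ref_ids) - 1)
    pca = PCA(n_components=n_comp)
    pca.fit(X_ref)
    all_ids = list(norm.zscores.columns)
    proj = pca.transform(norm.zscores.to_numpy().T)
    if n_comp == 1:  # a one-marker panel still defines an age axis
        proj = np.column_stack([proj[:, 0], np.zeros(len(proj))])
    coords = pd.DataFrame(proj, index=all_ids, columns=["PC1", "PC2"])

    meta = sample_meta.loc[coords.index.intersection(sample_meta.index)]
    ctrl = meta[meta["group"] == CONTROL]
    ages = sorted(ctrl["age_months"].unique())
    if control_ages is None:
        control_ages = (ages[0], ages[-1])
    young, old = control_ages
    med = {
        a: coords.loc[ctrl.index[ctrl["age_months"] == a], "PC1"].median()
        for a in (young, old)
    }
    flipped = bool(med[old] < med[young])
    if flipped:
        coords["PC1"] = -coords["PC1"]
    ev = pca.explained_variance_ratio_
    ev2 = float(ev[1]) if len(ev) > 1 else 0.0
    return AgeAxisProjection(coords, (float(ev[0]), ev2), flipped)


def median_axis_aging(
    projection: AgeAxisProjection,
    sample_meta: pd.DataFrame,
    group: str,
    from_age: int,
    to_age: int,
) -> float:
    """Metabolic-aging distance: median PC1 at ``to_age`` − median at ``from_age``."""
    out = []
    for a in (from_age, to_age):
        ids = sample_meta.index[
            (sample_meta["group"] == group) & (sample_meta["age_months"] == a)
        ]
        ids = projection.coords.index.intersection(ids)
        if len(ids) == 0:
            raise ValueError(f"no samples for ({group}, {a})")
        out.append(float(projection.coords.loc[ids, "PC1"].median()))
    return out[1] - out[0]


def aging_contrast_permutation(
    projection: AgeAxisProjection,
    sample_meta: pd.DataFrame,
    from_age: int,
    to_age: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test for slower molted metabolic aging on the PC1 axis.

    The statistic is the difference-of-differences of group medians:
    (control aging distance) − (molted aging distance) between the two
    ages.  Group labels are shuffled within each age cell and the statistic
    recomputed; extreme = |permuted| ≥ |observed|.
    """
    rng = _resolve_rng(seed)
    cells = {}
    for a in (from_age, to_age):
        ids_c = sample_meta.index[
            (sample_meta["group"] == CONTROL) & (sample_meta["age_months"] == a)
        ]
        ids_m = sample_meta.index[
            (sample_meta["group"] == MOLTED) & (sample_meta["age_months"] == a)
        ]
        pc1 = projection.coords["PC1"]
        vals = np.concatenate([pc1.loc[ids_c].to_numpy(), pc1.loc[ids_m].to_numpy()])
        if len(ids_c) == 0 or len(ids_m) == 0:
            raise ValueError(f"missing group cell at age {a}")
        cells[a] = (vals, len(ids_c))

    def stat(order_young: np.ndarray, order_old: np.ndarray) -> float:
        (vy, ny), (vo, no) = cells[from_age], cells[to_age]
        vy, vo = vy[order_young], vo[order_old]
        ctrl = np.median(vo[:no]) - np.median(vy[:ny])
        molt = np.median(vo[no:]) - np.median(vy[ny:])
        return abs(float(ctrl - molt))

    idy = np.arange(len(cells[from_age][0]))
    ido = np.arange(len(cells[to_age][0]))
    observed = stat(idy, ido)
    n_extreme = 0
    for _ in range(n_perm):
        if stat(rng.permutation(idy), rng.permutation(ido)) >= observed:
            n_extreme += 1
    return PermutationResult(observed, n_extreme, n_perm, "two-sided")


def _forest(seed, n_trees: int = RF_N_TREES) -> RandomForestRegressor:
    rs = int(_resolve_rng(seed).integers(0, 2**31 - 1)) if not isinstance(seed, int) else seed
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=RF_MAX_FEATURES,
        random_state=rs,
        n_jobs=1,
    )


def train_age_regressor(
    norm: NormalizedTable, ages: pd.Series, seed: int = 0
) -> RandomForestRegressor:
    """Random-forest age model trained on the reference (control) samples.

    ``ages`` maps sample id → chronological age in months; training uses
    exactly the normalization-reference samples.  Forest predictions are
    convex combinations of training targets, so they stay within the
    training-age range.
    """
    ref = norm.reference_samples
    y = ages.loc[ref].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training set needs at least 2 distinct ages")
    X = norm.zscores[ref].to_numpy().T
    model = _forest(seed)
    model.fit(X, y)
    return model


def predict_ages(
    model: RandomForestRegressor,
    norm: NormalizedTable,
    sample_meta: pd.DataFrame,
    sample_ids: list[str] | None = None,
) -> AgePredictionResult:
    """Predict ages for samples (z-scored by the training constants)."""
    ids = sample_ids if sample_ids is not None else list(norm.zscores.columns)
    X = norm.zscores[ids].to_numpy().T
    pred = model.predict(X)
    meta = sample_meta.loc[ids]
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "hen_id": meta["hen_id"].to_numpy(),
            "group": meta["group"].to_numpy(),
            "true_age": meta["age_months"].to_numpy(),
            "predicted_age": pred,
        }
    )
    medians = {
        (g, int(a)): float(sub["predicted_age"].median())
        for (g, a), sub in df.groupby(["group", "true_age"])
    }
    return AgePredictionResult(df, medians)


def _lasso_screen(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Indices of features with nonzero LASSO coefficients at the CV-chosen
    penalty; falls back to all features if the screen empties."""
    lasso = LassoCV(cv=5, random_state=seed, n_alphas=50, max_iter=5000)
    with np.errstate(all="ignore"):
        lasso.fit(X, y)
    idx = np.flatnonzero(lasso.coef_)
    return idx if len(idx) else np.arange(X.shape[1])


def loo_predict_efficiency(
    table: MetaboliteTable,
    efficiencies: pd.DataFrame,
    marker_ids: list[str],
    mode: str = "rfr",
    seed: int = 0,
    threshold: float = 0.5,
    n_trees: int = RF_N_TREES,
) -> PredictionEvaluation:
    """Leave-one-out efficiency prediction on control samples.

    For each held-out sample the remaining samples supply the z-scoring
    constants and train the model (``rfr``, or ``lasso_rfr_stack`` = LASSO
    feature screen feeding the forest), so the held-out sample never
    influences normalization, screening, or training.  Returns per-sample
    predictions, Pearson R with its p-value, and the capture rate: among
    samples with true efficiency > ``threshold``, the fraction predicted
    above it.
    """
    if mode not in ("rfr", "lasso_rfr_stack"):
        raise ValueError("mode must be 'rfr' or 'lasso_rfr_stack'")
    control = table.subset(group=CONTROL)
    eff_of = {
        (str(r.hen_id), int(r.month)): float(r.efficiency)
        for r in efficiencies.itertuples()
    }
    ids = [s.sample_id for s in control.samples]
    try:
        y = np.array([eff_of[(s.hen_id, s.sampling_month)] for s in control.samples])
    except KeyError as e:
        raise ValueError(f"sample missing efficiency phenotype: {e}") from e

    preds = np.empty(len(ids))
    for i, held in enumerate(ids):
        train_ids = [s for s in ids if s != held]
        norm = zscore_normalize(control, reference=train_ids, features=marker_ids)
        Xtr = norm.zscores[train_ids].to_numpy().T
        ytr = np.array([y[ids.index(s)] for s in train_ids])
        cols = np.arange(Xtr.shape[1])
        if mode == "lasso_rfr_stack":
            cols = _lasso_screen(Xtr, ytr, seed)
        model = _forest(seed, n_trees)
        model.fit(Xtr[:, cols], ytr)
        xh = norm.zscores[held].to_numpy()[cols]
        preds[i] = model.predict(xh.reshape(1, -1))[0]

    r, p = sps.pearsonr(y, preds)
    high = y > threshold
    capture = float(np.mean(preds[high] > threshold)) if high.any() else float("nan")
    df = pd.DataFrame({"sample_id": ids, "true": y, "predicted": preds})
    return PredictionEvaluation(df, float(r), float(p), capture, threshold)


def predict_efficiency_transfer(
    table: MetaboliteTable,
    efficiencies: pd.DataFrame,
    marker_ids: list[str],
    mode: str = "rfr",
    seed: int = 0,
    n_trees: int = RF_N_TREES,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Train on all control samples, predict molted samples.

    Molted samples are standardized with control-derived constants.
    Returns per-sample predictions and the predicted vs true ranges (the
    claim a transfer model supports is range-level).
    """
    control = table.subset(group=CONTROL)
    molted = table.subset(group=MOLTED)
    if set(molted.feature_ids) != set(control.feature_ids):
        raise ValueError("molted samples must share the feature universe")
    eff_of = {
        (str(r.hen_id), int(r.month)): float(r.efficiency)
        for r in efficiencies.itertuples()
    }
    ctrl_ids = [s.sample_id for s in control.samples]
    y = np.array([eff_of[(s.hen_id, s.sampling_month)] for s in control.samples])
    norm = zscore_normalize(control, reference=ctrl_ids, features=marker_ids)
    Xtr = norm.zscores[ctrl_ids].to_numpy().T
    cols = np.arange(Xtr.shape[1])
    if mode == "lasso_rfr_stack":
        cols = _lasso_screen(Xtr, y, seed)
    model = _forest(seed, n_trees)
    model.fit(Xtr[:, cols], y)

    molt_ids = [s.sample_id for s in molted.samples]
    if not molt_ids:
        return pd.DataFrame(columns=["sample_id", "true", "predicted"]), {}
    Z = norm.transform(molted.intensities.loc[marker_ids])
    preds = model.predict(Z[molt_ids].to_numpy().T[:, cols])
    true = np.array([eff_of.get((s.hen_id, s.sampling_month), np.nan) for s in molted.samples])
    df = pd.DataFrame({"sample_id": molt_ids, "true": true, "predicted": preds})
    ranges = {
        "predicted_min": float(np.min(preds)),
        "predicted_max": float(np.max(preds)),
        "true_min": float(np.nanmin(true)),
        "true_max": float(np.nanmax(true)),
    }
    return df, ranges
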