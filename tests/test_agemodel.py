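"""Age- and efficiency-model tests: normalization contracts, PCA axis
conventions, leakage controls, and planted-signal prediction quality."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import metanoise as mn
from metanoise import agemodel
from metanoise.cohort import CONTROL, MOLTED, MetaboliteTable


@pytest.fixture(scope="module")
def model_inputs(default_cohort):
    table, log, _, truth = default_cohort
    aging = mn.select_aging_biomarkers(table, ages=(21, 27, 33))
    meta = table.sample_frame
    ctrl_ids = [
        s.sample_id
        for s in table.samples
        if s.group == CONTROL and s.age_months in (21, 27, 33)
    ]
    norm = agemodel.zscore_normalize(table, ctrl_ids, features=aging.feature_ids)
    return table, meta, aging, norm, ctrl_ids, truth


# ------------------------------------------------------------ normalization


def test_zscore_reference_contract(model_inputs):
    _, _, _, norm, ctrl_ids, _ = model_inputs
    ref = norm.zscores[ctrl_ids]
    assert np.allclose(ref.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(ref.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_zscore_idempotent_and_mean_sample(default_cohort):
    table, _, _, _ = default_cohort
    sub = MetaboliteTable(
        table.intensities.iloc[:40],
        table.samples,
        table.chemical_group.iloc[:40],
    )
    norm = agemodel.zscore_normalize(sub)
    # a held-out sample equal to the reference mean vector maps to zeros
    mean_vec = sub.intensities.mean(axis=1)
    z = norm.transform(mean_vec.to_frame("mean_sample"))
    assert np.allclose(z["mean_sample"], 0.0, atol=1e-12)


def test_zscore_zero_variance_errors(default_cohort):
    table, _, _, _ = default_cohort
    mat = table.intensities.iloc[:5].copy()
    mat.iloc[2] = 7.0
    flat = MetaboliteTable(mat, table.samples, table.chemical_group.iloc[:5])
    with pytest.raises(ValueError, match=mat.index[2]):
        agemodel.zscore_normalize(flat)


# --------------------------------------------------------------------- PCA


def test_pca_age_axis_tracks_age(model_inputs):
    _, meta, _, norm, _, _ = model_inputs
    proj = agemodel.pca_age_axis(norm, meta, control_ages=(21, 33))
    ev1, ev2 = proj.explained_variance
    assert 0 <= ev2 <= ev1 <= 1
    ctrl = meta[meta["group"] == CONTROL]
    rho = sps.spearmanr(
        proj.coords.loc[ctrl.index, "PC1"], ctrl["age_months"]
    ).statistic
    assert abs(rho) >= 0.9
    # enforced orientation: older control median to the right
    med = {
        a: proj.coords.loc[ctrl.index[ctrl["age_months"] == a], "PC1"].median()
        for a in (21, 33)
    }
    assert med[33] > med[21]


def test_pca_duplication_invariance(model_inputs):
    """Duplicating every reference sample leaves axes and EV unchanged."""
    table, meta, aging, norm, ctrl_ids, _ = model_inputs
    dup = pd.concat(
        [norm.zscores[ctrl_ids], norm.zscores[ctrl_ids].add_suffix("_dup")], axis=1
    )
    meta_dup = pd.concat([meta.loc[ctrl_ids], meta.loc[ctrl_ids].set_axis([f"{i}_dup" for i in ctrl_ids])])
    norm_dup = agemodel.NormalizedTable(dup, norm.mean, norm.sd, list(dup.columns))
    p1 = agemodel.pca_age_axis(norm, meta, control_ages=(21, 33))
    p2 = agemodel.pca_age_axis(norm_dup, meta_dup, control_ages=(21, 33))
    assert p2.explained_variance == pytest.approx(p1.explained_variance, abs=1e-9)
    common = [c for c in ctrl_ids]
    assert np.allclose(
        p2.coords.loc[common, "PC1"], p1.coords.loc[common, "PC1"], atol=1e-8
    )


def test_median_axis_aging_contract(model_inputs):
    _, meta, _, norm, _, _ = model_inputs
    proj = agemodel.pca_age_axis(norm, meta, control_ages=(21, 33))
    ctrl = agemodel.median_axis_aging(proj, meta, CONTROL, 21, 33)
    molt = agemodel.median_axis_aging(proj, meta, MOLTED, 21, 33)
    # molted hens travel less along the age axis than controls
    assert 0 < molt < ctrl
    # flipping the axis negates the distance
    flipped = agemodel.AgeAxisProjection(
        proj.coords.assign(PC1=-proj.coords["PC1"]),
        proj.explained_variance,
        not proj.orientation_flipped,
    )
    assert agemodel.median_axis_aging(flipped, meta, CONTROL, 21, 33) == pytest.approx(
        -ctrl
    )
    with pytest.raises(ValueError, match="no samples"):
        agemodel.median_axis_aging(proj, meta, MOLTED, 23, 33)


def test_aging_contrast_permutation(model_inputs):
    _, meta, _, norm, _, _ = model_inputs
    proj = agemodel.pca_age_axis(norm, meta, control_ages=(21, 33))
    res = agemodel.aging_contrast_permutation(proj, meta, 21, 33, n_perm=400, seed=3)
    assert res.p_value <= 0.05  # attenuation 2/3 is detectable on the axis


# ------------------------------------------------------------ age regressor


def test_age_regressor_predictions(model_inputs):
    _, meta, _, norm, ctrl_ids, _ = model_inputs
    model = agemodel.train_age_regressor(norm, meta["age_months"].astype(float), seed=7)
    pred = agemodel.predict_ages(model, norm, meta)
    # forest predictions are convex combinations of training targets
    assert pred.predictions["predicted_age"].between(21, 33).all()
    med = pred.group_medians
    # training-cohort medians recover truth within +/-2 months
    for a in (21, 27, 33):
        assert med[(CONTROL, a)] == pytest.approx(a, abs=2)
    # molted hierarchy is correct and the span is compressed vs control
    assert med[(MOLTED, 21)] < med[(MOLTED, 27)] < med[(MOLTED, 33)]
    molt_span = med[(MOLTED, 33)] - med[(MOLTED, 21)]
    ctrl_span = med[(CONTROL, 33)] - med[(CONTROL, 21)]
    assert molt_span < ctrl_span


def test_age_regressor_single_age_errors(model_inputs):
    table, meta, aging, _, _, _ = model_inputs
    ids21 = [
        s.sample_id
        for s in table.samples
        if s.group == CONTROL and s.age_months == 21
    ]
    norm21 = agemodel.zscore_normalize(table, ids21, features=aging.feature_ids)
    with pytest.raises(ValueError, match="distinct ages"):
        agemodel.train_age_regressor(norm21, meta["age_months"].astype(float), seed=0)


# ----------------------------------------------------- efficiency prediction


def test_loo_leakage_control_perfect_feature(default_cohort, default_efficiency):
    """Efficiency copied into a feature gives near-perfect LOO prediction."""
    table, _, _, _ = default_cohort
    ctrl = table.subset(group=CONTROL)
    eff_of = {
        (r.hen_id, r.month): r.efficiency for r in default_efficiency.itertuples()
    }
    tracker = np.array(
        [eff_of[(s.hen_id, s.sampling_month)] + 0.05 for s in ctrl.samples]
    )
    mat = pd.concat(
        [
            ctrl.intensities.iloc[:10],
            pd.DataFrame([tracker], index=["tracker"], columns=ctrl.intensities.columns),
        ]
    )
    table2 = MetaboliteTable(mat, ctrl.samples, pd.Series("x", index=mat.index))
    ev = agemodel.loo_predict_efficiency(
        table2, default_efficiency, ["tracker"], seed=0, n_trees=60
    )
    assert ev.pearson_r >= 0.95


def test_loo_no_leakage_from_held_out_sample(default_cohort, default_efficiency):
    """A held-out sample's fold is bit-identical to a model built without
    it: reconstructing the fold manually (normalize by the remaining
    samples, train on them, predict the held-out one) reproduces the LOO
    prediction exactly, so the held-out sample never enters its own fold's
    normalization or training."""
    table, _, _, _ = default_cohort
    ctrl = table.subset(group=CONTROL, ages=[21, 27])
    markers = list(ctrl.feature_ids[:25])
    ev = agemodel.loo_predict_efficiency(
        ctrl, default_efficiency, markers, seed=1, n_trees=40
    )
    eff_of = {
        (r.hen_id, r.month): r.efficiency for r in default_efficiency.itertuples()
    }
    ids = [s.sample_id for s in ctrl.samples]
    for victim in (ids[0], ids[-1]):
        train_ids = [s for s in ids if s != victim]
        norm = agemodel.zscore_normalize(ctrl, reference=train_ids, features=markers)
        Xtr = norm.zscores[train_ids].to_numpy().T
        ytr = np.array(
            [
                eff_of[(s.hen_id, s.sampling_month)]
                for s in ctrl.samples
                if s.sample_id != victim
            ]
        )
        model = agemodel._forest(1, 40)
        model.fit(Xtr, ytr)
        manual = model.predict(norm.zscores[victim].to_numpy().reshape(1, -1))[0]
        loo_pred = ev.predictions.set_index("sample_id").loc[victim, "predicted"]
        assert loo_pred == pytest.approx(manual, abs=1e-12)


def test_loo_planted_signal_and_null(default_cohort, default_efficiency):
    """Collective markers predict efficiency (R >= 0.5 at the reference
    seed); label-shuffled nulls show no signal (mean |R| <= 0.2)."""
    table, _, _, _ = default_cohort
    ctrl = table.subset(group=CONTROL)
    laying = mn.select_laying_biomarkers(ctrl, default_efficiency)
    markers = laying.feature_ids[:60]
    ev = agemodel.loo_predict_efficiency(
        ctrl, default_efficiency, markers, seed=2, n_trees=120
    )
    assert ev.pearson_r >= 0.5
    assert 0 <= ev.capture_rate <= 1

    rng = np.random.default_rng(5)
    rs = []
    eff = default_efficiency.copy()
    ctrl_small = table.subset(group=CONTROL, ages=[21, 27, 33])
    for _ in range(6):
        shuffled = eff.copy()
        shuffled["efficiency"] = rng.permutation(shuffled["efficiency"].to_numpy())
        evn = agemodel.loo_predict_efficiency(
            ctrl_small, shuffled, markers[:25], seed=3, n_trees=40
        )
        rs.append(abs(evn.pearson_r))
    assert np.mean(rs) <= 0.2


def test_transfer_predictions(default_cohort, default_efficiency):
    table, _, _, _ = default_cohort
    laying = mn.select_laying_biomarkers(table.subset(group=CONTROL), default_efficiency)
    preds, ranges = agemodel.predict_efficiency_transfer(
        table, default_efficiency, laying.feature_ids[:60], seed=4, n_trees=120
    )
    assert len(preds) == sum(1 for s in table.samples if s.group == MOLTED)
    # range-level capture for confidently-laying molted samples
    post = preds[preds["true"] >= 0.6]
    frac_in = np.mean((post["predicted"] >= 0.5) & (post["predicted"] <= 1.05))
    assert frac_in >= 0.8
    assert ranges["predicted_min"] >= 0.0 and ranges["predicted_max"] <= 1.05


def test_transfer_identity_and_empty(default_cohort, default_efficiency):
    table, _, _, _ = default_cohort
    ctrl = table.subset(group=CONTROL)
    markers = list(ctrl.feature_ids[:15])
    # no molted samples -> empty output
    preds, ranges = agemodel.predict_efficiency_transfer(
        ctrl, default_efficiency, markers, seed=0, n_trees=30
    )
    assert preds.empty and ranges == {}
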