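"""End-to-end reproducible runs: simulate → phenotype → select → model → noise.

:func:`run_pipeline` executes the full chain under one :class:`RunConfig`,
writes every stage's plain-text outputs into the run directory, and returns
(and writes) a machine-readable summary with biomarker counts, recovery
against planted truth, age-model medians, noise trajectories and all
p-values, alongside the config and its hash.  Identical configs produce
byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import agemodel, biomarkers, noise, phenotypes, stats
from .cohort import CONTROL, MOLTED
from .simulate import MOLT_MONTHS, RECOVERY_MONTH, SimConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    q_aging: float = 0.1
    q_laying: float = 0.1
    model_mode: str = "rfr"  # or "lasso_rfr_stack"
    n_perm: int = 1000
    noise_window_months: int = 7
    laying_include_validation_age: bool = True
    include_aging_marker_loo: bool = True
    outdir: str | None = None

    def to_yaml_text(self) -> str:
        d = asdict(self)
        d["sim"]["n_timepoints_ages"] = list(d["sim"]["n_timepoints_ages"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("sim", {})
        if "n_timepoints_ages" in sim:
            sim["n_timepoints_ages"] = tuple(sim["n_timepoints_ages"])
        known = {f.name for f in fields(cls)} - {"sim"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(sim=SimConfig(**sim), **d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml_text().encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"[{name}] {e}") from e
        return wrapper
    return deco


def _round(x, nd=6):
    """Round floats and stringify keys so the summary survives a JSON
    round-trip unchanged."""
    if isinstance(x, dict):
        return {str(k): _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full analysis chain on one simulated cohort.

    Returns the summary dict; when an output directory is given (argument
    or config), all stage outputs and ``summary.json`` are written there.
    """
    out = Path(outdir) if outdir is not None else (
        Path(config.outdir) if config.outdir else None
    )
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.sim.seed)
    perm_seed = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    # ---------------------------------------------------------------- simulate
    table, log, cytokines, truth = _stage("simulate")(simulate_cohort)(config.sim)
    truth.validate()
    ages = list(config.sim.n_timepoints_ages)
    a1, a_val, a2, a3 = ages[0], ages[1], ages[-2], ages[-1]

    # --------------------------------------------------------------- phenotype
    @_stage("phenotypes")
    def phenotype_stage():
        eff = phenotypes.efficiency_table(log)
        ctrl_hens = [h for h, g in log.group_of.items() if g == CONTROL]
        molt_hens = [h for h, g in log.group_of.items() if g == MOLTED]
        # sterility analysis applies to the untreated arm only: the molt
        # itself imposes a >21-day laying pause on every treated hen
        ctrl_surv = [
            r for r in phenotypes.survival_records(log) if r.hen_id in ctrl_hens
        ]
        molt_deaths = sum(1 for h in molt_hens if h in log.death_day)
        ctrl_pct, ctrl_frac = phenotypes.mortality_fraction(ctrl_surv)
        table22 = phenotypes.sterility_mortality_table(ctrl_surv)
        fisher_p = stats.fisher_exact_2x2(table22)
        binom_p = stats.binomial_two_group_survival_test(
            sum(r.died for r in ctrl_surv), len(ctrl_surv), molt_deaths, len(molt_hens)
        )
        med_eff = {
            g: {
                m: phenotypes.cohort_median_efficiency(
                    log, [h for h in log.hen_ids if log.group_of[h] == g], m
                )
                for m in log.months()
            }
            for g in (CONTROL, MOLTED)
        }
        return eff, {
            "control_mortality_percent": ctrl_pct,
            "control_mortality_fraction": ctrl_frac,
            "molted_mortality_percent": int(round(100 * molt_deaths / len(molt_hens))),
            "sterility_mortality_table": table22.tolist(),
            "fisher_p": fisher_p,
            "binomial_survival_p": binom_p,
            "median_efficiency": med_eff,
        }

    eff, pheno_summary = phenotype_stage()

    # --------------------------------------------------------------- selection
    @_stage("select-biomarkers")
    def selection_stage():
        aging = biomarkers.select_aging_biomarkers(
            table, q_cutoff=config.q_aging, ages=(a1, a2, a3)
        )
        laying_ages = ages if config.laying_include_validation_age else [a1, a2, a3]
        laying = biomarkers.select_laying_biomarkers(
            table.subset(group=CONTROL, ages=laying_ages), eff, q_cutoff=config.q_laying
        )
        common = biomarkers.common_markers(aging, laying, table)
        return aging, laying, common, {
            "n_aging": len(aging),
            "n_laying": len(laying),
            "n_common": len(common),
            "aging_recovery": biomarkers.recovery_metrics(
                aging.feature_ids, truth.aging_feature_ids
            ),
            "laying_recovery": biomarkers.recovery_metrics(
                laying.feature_ids, truth.laying_feature_ids
            ),
        }

    aging_set, laying_set, common_set, select_summary = selection_stage()

    # --------------------------------------------------------------- age model
    @_stage("age-model")
    def age_stage():
        meta = table.sample_frame
        ctrl_train_ids = [
            s.sample_id
            for s in table.samples
            if s.group == CONTROL and s.age_months in (a1, a2, a3)
        ]
        marker_ids = aging_set.feature_ids or table.feature_ids
        norm = agemodel.zscore_normalize(table, ctrl_train_ids, features=marker_ids)
        proj = agemodel.pca_age_axis(norm, meta, control_ages=(a1, a3))
        axis = {
            g: agemodel.median_axis_aging(proj, meta, g, a1, a3)
            for g in (CONTROL, MOLTED)
        }
        contrast = agemodel.aging_contrast_permutation(
            proj, meta, a1, a3, n_perm=config.n_perm, seed=perm_seed()
        )
        model = agemodel.train_age_regressor(
            norm, meta["age_months"].astype(float), seed=perm_seed()
        )
        pred = agemodel.predict_ages(model, norm, meta)
        med = pred.group_medians
        spans = {
            g: med[(g, a3)] - med[(g, a1)]
            for g in (CONTROL, MOLTED)
            if (g, a1) in med and (g, a3) in med
        }
        return {
            "pc_explained_variance": list(proj.explained_variance),
            "axis_aging_distance": axis,
            "axis_contrast_p": contrast.p_value,
            "predicted_age_medians": {
                f"{g}_t{a}": v for (g, a), v in sorted(med.items())
            },
            "predicted_age_span": spans,
            "validation_median_predicted_age": med.get((CONTROL, a_val)),
        }

    age_summary = age_stage()

    # --------------------------------------------------------- efficiency model
    @_stage("predict-efficiency")
    def efficiency_stage():
        laying_ages = ages if config.laying_include_validation_age else [a1, a2, a3]
        ctrl = table.subset(group=CONTROL, ages=laying_ages)
        marker_ids = laying_set.feature_ids or table.feature_ids
        loo = agemodel.loo_predict_efficiency(
            ctrl, eff, marker_ids, mode=config.model_mode, seed=perm_seed()
        )
        _, transfer = agemodel.predict_efficiency_transfer(
            table, eff, marker_ids, mode=config.model_mode, seed=perm_seed()
        )
        out = {
            "loo_pearson_r": loo.pearson_r,
            "loo_p": loo.p_value,
            "loo_capture_rate": loo.capture_rate,
            "transfer_range": transfer,
        }
        if config.include_aging_marker_loo and aging_set.feature_ids:
            loo_aging = agemodel.loo_predict_efficiency(
                table.subset(group=CONTROL, ages=[a1, a2, a3]),
                eff,
                aging_set.feature_ids,
                mode=config.model_mode,
                seed=perm_seed(),
            )
            out["loo_aging_markers_pearson_r"] = loo_aging.pearson_r
            out["loo_aging_markers_p"] = loo_aging.p_value
        return out

    eff_summary = efficiency_stage()

    # -------------------------------------------------------------------- noise
    @_stage("noise")
    def noise_stage():
        summaries, comparisons = noise.noise_trajectory(
            table, (CONTROL, MOLTED), ages, n_perm=config.n_perm, seed=perm_seed()
        )
        window = list(range(RECOVERY_MONTH, RECOVERY_MONTH + config.noise_window_months))
        alive_through = [
            h
            for h in log.hen_ids
            if log.death_day.get(h, 10**9) > log.month_span(window[-1])[1]
        ]
        ctrl_ids = [h for h in alive_through if log.group_of[h] == CONTROL]
        molt_ids = [h for h in alive_through if log.group_of[h] == MOLTED]
        slope_test = noise.reproduction_slope_test(
            eff, ctrl_ids, molt_ids, window, n_perm=config.n_perm, seed=perm_seed()
        )
        rep_noise = {
            g: [
                {"month": r.month, "cv": r.cv}
                for r in noise.reproduction_noise_trajectory(
                    eff[eff["hen_id"].isin(alive_through)], g, window
                )
            ]
            for g in (CONTROL, MOLTED)
        }
        _, cyto_p = noise.cytokine_panel_comparison(
            cytokines, (CONTROL, MOLTED), [a1, a2, a3],
            n_perm=config.n_perm, seed=perm_seed(),
        )
        return {
            "metabolic_noise": {
                f"{s.group}_t{s.age_months}": s.median_cv for s in summaries
            },
            "metabolic_noise_p": {f"t{a}": r.p_value for a, r in comparisons.items()},
            "reproduction_noise": rep_noise,
            "reproduction_slope_p": slope_test.p_value,
            "reproduction_slope_diff": slope_test.observed_stat,
            "cytokine_p": {f"t{a}": r.p_value for a, r in cyto_p.items()},
        }

    noise_summary = noise_stage()

    summary = _round(
        {
            "config_hash": config.config_hash,
            "seed": config.sim.seed,
            "n_samples": len(table.samples),
            "molt_months": list(MOLT_MONTHS),
            "phenotypes": pheno_summary,
            "biomarkers": select_summary,
            "age_model": age_summary,
            "efficiency_model": eff_summary,
            "noise": noise_summary,
        }
    )

    if out is not None:
        _stage("report")(_write_outputs)(
            out, config, table, log, cytokines, truth, eff,
            aging_set, laying_set, common_set, summary,
        )
    return summary


def _write_outputs(out, config, table, log, cytokines, truth, eff,
                   aging_set, laying_set, common_set, summary) -> None:
    (out / "config.yaml").write_text(config.to_yaml_text())
    table.to_tsv(out / "metabolites.tsv", out / "samples.tsv")
    log.to_csv(out / "laying.csv")
    cytokines.to_csv(out / "cytokines.csv", index=False)
    truth.to_json(out / "truth.json")
    eff.to_csv(out / "efficiency.tsv", sep="\t", index=False)
    aging_set.to_json(out / "aging_biomarkers.json")
    aging_set.to_tsv(out / "aging_biomarkers.tsv")
    laying_set.to_json(out / "laying_biomarkers.json")
    laying_set.to_tsv(out / "laying_biomarkers.tsv")
    common_set.to_json(out / "common_biomarkers.json")
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=False))
    (out / "run.log").write_text(
        f"config_hash={summary['config_hash']}\nseed={summary['seed']}\n"
        f"stages=simulate,phenotypes,select-biomarkers,age-model,"
        f"predict-efficiency,noise,report\n"
    )
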