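"""Synthetic longitudinal hen-cohort generator with queryable ground truth.

Emulates the three input kinds the analysis consumes — a feature-by-sample
plasma-metabolite intensity table, daily egg-laying logs, and a 9-channel
cytokine panel — for a two-arm design: *control* hens fed ad libitum, and
*molted* hens subjected to a transient severe caloric-restriction protocol
at 22–23 months of age.  The planted structure mirrors what the analyses
assume:

* a subset of features drifts monotonically with age (slower, by
  ``molt_attenuation``, in molted hens after the molt);
* a subset of features co-varies with each hen's latent fecundity
  *relative to its group-age mean* (so reproduction markers carry no
  built-in age trend of their own);
* per-feature multiplicative noise has a coefficient of variation that
  grows with age in controls and is reduced by ``cv_molt_reduction`` in
  molted hens after the molt;
* laying efficiency declines logistically per hen, collapses to zero
  during the molt months and recovers toward ``molt_recovery_efficiency``;
* sterility (21 consecutive zero-egg days) couples to mortality.

Every random draw flows through one seeded generator, so identical configs
produce bit-identical cohorts.  :class:`SimTruth` records all planted
structure for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CONTROL, MOLTED, LayingLog, MetaboliteTable, SampleMeta, month_boundaries

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "select_metabolomics_subset"]

#: molt protocol occupies these age months (zero egg production)
MOLT_MONTHS = (22, 23)
#: steady state post-molt resumes at this age month
RECOVERY_MONTH = 24
N_CYTOKINES = 9
CYTOKINE_AGES = (21, 27, 33)


@dataclass(frozen=True)
class SimConfig:
    """Study-design constants and planted effect sizes.

    Defaults encode the emulated study: 32 hens per arm, 693 metabolic
    features, blood sampling at 21/23/27/33 months (t23 control-only),
    12-hen metabolomics subsets, aging-rate attenuation of 2/3 in molted
    hens, and 90% median post-molt laying efficiency.
    """

    seed: int = 0
    n_hens_per_group: int = 32
    n_features: int = 693
    n_timepoints_ages: tuple[int, ...] = (21, 23, 27, 33)
    frac_aging_features: float = 0.3
    frac_laying_features: float = 0.27
    aging_effect_size: float = 1.0  # median shift per 12 months, in baseline SDs
    molt_attenuation: float = 2.0 / 3.0
    cv_base: float = 0.25
    cv_age_slope: float = 0.005  # per month, controls
    cv_molt_reduction: float = 0.05
    efficiency_decline_per_month: float = 0.02
    molt_recovery_efficiency: float = 0.9
    sterility_mortality_coupling: float = 0.7
    # -- world parameters not pinned by the emulated design (see docs) --
    n_metabolomics_subset: int = 12
    exclude_top_fraction: float = 0.10
    laying_effect_size: float = 2.0  # log-intensity per unit efficiency deviation
    sterility_rate_control: float = 0.45
    sterility_rate_molted: float = 0.15
    background_mortality: float = 0.05
    baseline_efficiency_mean: float = 0.85
    baseline_efficiency_sd: float = 0.08
    recovery_efficiency_sd: float = 0.05
    cytokine_decline_per_year: float = 0.4
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "frac_aging_features",
            "frac_laying_features",
            "exclude_top_fraction",
            "molt_recovery_efficiency",
            "sterility_mortality_coupling",
            "sterility_rate_control",
            "sterility_rate_molted",
            "background_mortality",
            "dropout_rate",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be a fraction in [0, 1]")
        for name in ("aging_effect_size", "cv_base", "cv_age_slope",
                     "cv_molt_reduction", "efficiency_decline_per_month",
                     "laying_effect_size"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 < self.molt_attenuation <= 1.0):
            raise ValueError("molt_attenuation must lie in (0, 1]")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        ages = tuple(self.n_timepoints_ages)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        object.__setattr__(self, "n_timepoints_ages", ages)

    # ------------------------------------------------------------- config IO

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["n_timepoints_ages"] = list(d["n_timepoints_ages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "n_timepoints_ages" in d:
            d["n_timepoints_ages"] = tuple(d["n_timepoints_ages"])
        return cls(**d)


@dataclass
class SimTruth:
    """Planted ground truth of one simulated cohort."""

    aging_direction: dict[str, int]  # feature id -> +1 / -1
    laying_sign: dict[str, int]  # feature id -> +1 / -1
    fecundity: dict[str, dict[int, float]]  # hen -> month -> latent fecundity
    sterility_onset_month: dict[str, int]
    death_month: dict[str, int]
    metabolomics_subsets: dict[str, dict[int, list[str]]]  # group -> age -> hens
    planted_cv: dict[str, dict[int, float]]  # group -> age -> CV
    molt_attenuation: float

    @property
    def aging_feature_ids(self) -> set[str]:
        return set(self.aging_direction)

    @property
    def laying_feature_ids(self) -> set[str]:
        return set(self.laying_sign)

    def validate(self) -> None:
        for hen, death in self.death_month.items():
            onset = self.sterility_onset_month.get(hen)
            if onset is not None and death <= onset:
                raise ValueError(f"hen {hen}: death month {death} <= sterility onset {onset}")

    def to_json(self, path: str | Path) -> None:
        d = {
            "aging_direction": self.aging_direction,
            "laying_sign": self.laying_sign,
            "fecundity": {h: {str(m): v for m, v in t.items()} for h, t in self.fecundity.items()},
            "sterility_onset_month": self.sterility_onset_month,
            "death_month": self.death_month,
            "metabolomics_subsets": {
                g: {str(a): hens for a, hens in ages.items()}
                for g, ages in self.metabolomics_subsets.items()
            },
            "planted_cv": {
                g: {str(a): cv for a, cv in ages.items()} for g, ages in self.planted_cv.items()
            },
            "molt_attenuation": self.molt_attenuation,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            aging_direction={k: int(v) for k, v in d["aging_direction"].items()},
            laying_sign={k: int(v) for k, v in d["laying_sign"].items()},
            fecundity={h: {int(m): v for m, v in t.items()} for h, t in d["fecundity"].items()},
            sterility_onset_month={k: int(v) for k, v in d["sterility_onset_month"].items()},
            death_month={k: int(v) for k, v in d["death_month"].items()},
            metabolomics_subsets={
                g: {int(a): hens for a, hens in ages.items()}
                for g, ages in d["metabolomics_subsets"].items()
            },
            planted_cv={
                g: {int(a): cv for a, cv in ages.items()} for g, ages in d["planted_cv"].items()
            },
            molt_attenuation=float(d["molt_attenuation"]),
        )


# --------------------------------------------------------------------------
# latent fecundity
# --------------------------------------------------------------------------

def _logistic_fecundity(baseline: float, month: float, start_month: int, slope: float) -> float:
    """Logistic-declining latent fecundity anchored at ``baseline`` at study start.

    The logistic shape scale is set so the local decline near the operating
    point (~0.8 efficiency) matches ``slope`` per month; output is bounded
    in (0, 1) by construction.
    """
    s = max(0.8 * (1 - 0.8) / slope, 1e-9) if slope > 0 else np.inf
    if not np.isfinite(s):
        return baseline
    b = min(max(baseline, 1e-6), 1 - 1e-6)
    c = start_month + s * np.log(b / (1.0 - b))
    return float(1.0 / (1.0 + np.exp((month - c) / s)))


def planted_cv(config: SimConfig, group: str, age: float) -> float:
    """The CV the generator plants for one (group, age) cell."""
    start = config.n_timepoints_ages[0]
    cv = config.cv_base + config.cv_age_slope * (age - start)
    if group == MOLTED and age >= RECOVERY_MONTH:
        cv -= config.cv_molt_reduction
    return max(cv, 0.02)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def select_metabolomics_subset(
    log: LayingLog,
    group: str,
    n: int,
    exclude_top_fraction: float,
    seed: int | np.random.Generator,
    month: int | None = None,
    eligible: list[str] | None = None,
) -> list[str]:
    """Seed-reproducible choice of hens for metabolomics profiling.

    With ``exclude_top_fraction`` > 0 (the treated arm), hens whose
    efficiency at ``month`` lies strictly above the
    (1 − exclude_top_fraction) quantile are removed first — a threshold on
    the value, so hens tying with the quantile are kept — and ``n`` hens
    are drawn uniformly from the remainder.  With 0 (controls) the draw is
    purely random.
    """
    from .phenotypes import laying_efficiency

    month = month if month is not None else min(log.month_starts)
    hens = sorted(
        h
        for h in (eligible if eligible is not None else log.hen_ids)
        if log.group_of.get(h) == group
    )
    if exclude_top_fraction > 0:
        effs = np.array([laying_efficiency(log, h, month).efficiency for h in hens])
        cut = float(np.quantile(effs, 1.0 - exclude_top_fraction))
        hens = [h for h, e in zip(hens, effs) if e <= cut]
    if len(hens) < n:
        raise ValueError(f"only {len(hens)} eligible hens for a subset of {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picked = rng.choice(len(hens), size=n, replace=False)
    return [hens[i] for i in sorted(picked)]


def simulate_cohort(
    config: SimConfig,
) -> tuple[MetaboliteTable, LayingLog, pd.DataFrame, SimTruth]:
    """Generate one longitudinal cohort.

    Returns ``(metabolite_table, laying_log, cytokine_panel, truth)``.  The
    metabolite table contains the study's sampling design: fresh random
    control subsets at every timepoint (including the t23 validation
    cohort) and one longitudinally tracked molted subset at t21/t27/t33.
    The cytokine panel is long-form (hen_id, group, age_months, channel,
    value) for all hens alive at each cytokine age.
    """
    rng = np.random.default_rng(config.seed)
    ages = list(config.n_timepoints_ages)
    start_month, last_age = ages[0], ages[-1]
    n_months = last_age - start_month + 1
    month_starts = month_boundaries(start_month, n_months)
    months = list(range(start_month, last_age + 1))
    last_day = month_starts[last_age + 1] - 1

    hens = [f"c{i:03d}" for i in range(config.n_hens_per_group)] + [
        f"m{i:03d}" for i in range(config.n_hens_per_group)
    ]
    group_of = {h: (CONTROL if h.startswith("c") else MOLTED) for h in hens}

    # --- per-hen latent parameters -------------------------------------
    baseline = {
        h: float(np.clip(rng.normal(config.baseline_efficiency_mean,
                                    config.baseline_efficiency_sd), 0.35, 0.98))
        for h in hens
    }
    recovery = {
        h: float(np.clip(rng.normal(config.molt_recovery_efficiency,
                                    config.recovery_efficiency_sd), 0.5, 1.0))
        for h in hens
        if group_of[h] == MOLTED
    }

    # --- sterility and mortality ---------------------------------------
    sterility_onset_day: dict[str, int] = {}
    death_day: dict[str, int] = {}
    for h in hens:
        rate = (
            config.sterility_rate_control
            if group_of[h] == CONTROL
            else config.sterility_rate_molted
        )
        if rng.random() < rate:
            onset_month = int(rng.integers(RECOVERY_MONTH, last_age))
            onset_day = month_starts[onset_month] + int(
                rng.integers(0, month_starts[onset_month + 1] - month_starts[onset_month])
            )
            sterility_onset_day[h] = onset_day
            if rng.random() < config.sterility_mortality_coupling:
                # death follows sterility within ~3 months, never before the
                # 21-day sterile stretch is observable nor within the onset
                # month itself
                d = onset_day + 21 + int(rng.integers(0, 70))
                death_day[h] = min(max(d, month_starts[onset_month + 1]), last_day)
        elif rng.random() < config.background_mortality:
            death_day[h] = int(rng.integers(month_starts[RECOVERY_MONTH + 1], last_day + 1))

    def fecundity_at(h: str, month: int) -> float:
        """Latent laying propensity of a live, non-sterile hen at an age month."""
        if group_of[h] == CONTROL:
            return _logistic_fecundity(
                baseline[h], month, start_month, config.efficiency_decline_per_month
            )
        if month in MOLT_MONTHS:
            return 0.0
        if month >= RECOVERY_MONTH:
            rate = config.efficiency_decline_per_month * config.molt_attenuation
            return float(max(recovery[h] - rate * (month - RECOVERY_MONTH), 0.0))
        return _logistic_fecundity(
            baseline[h], month, start_month, config.efficiency_decline_per_month
        )

    fecundity = {h: {m: fecundity_at(h, m) for m in months} for h in hens}

    # --- daily laying log ----------------------------------------------
    frames = []
    for h in hens:
        end = min(death_day.get(h, last_day + 1), last_day + 1)
        days = np.arange(0, end)
        month_of_day = np.searchsorted(
            [month_starts[m] for m in months[1:]] + [last_day + 1], days, side="right"
        )
        probs = np.array([fecundity[h][months[mi]] for mi in month_of_day])
        if h in sterility_onset_day:
            probs[days >= sterility_onset_day[h]] = 0.0
        eggs = (rng.random(len(days)) < probs).astype(int)
        frames.append(pd.DataFrame({"hen_id": h, "day": days, "egg": eggs}))
    log = LayingLog(
        pd.concat(frames, ignore_index=True),
        death_day=dict(death_day),
        month_starts=month_starts,
        group_of=dict(group_of),
    )

    # --- metabolomics subsets ------------------------------------------
    survivors = [h for h in hens if h not in death_day]
    alive_at = {
        a: [h for h in hens if death_day.get(h, last_day + 1) > month_starts[a]]
        for a in ages
    }
    subsets: dict[str, dict[int, list[str]]] = {CONTROL: {}, MOLTED: {}}
    for a in ages:
        subsets[CONTROL][a] = select_metabolomics_subset(
            log,
            CONTROL,
            config.n_metabolomics_subset,
            0.0,
            rng,
            month=start_month,
            eligible=[h for h in alive_at[a] if group_of[h] == CONTROL],
        )
    molted_tracked = select_metabolomics_subset(
        log,
        MOLTED,
        config.n_metabolomics_subset,
        config.exclude_top_fraction,
        rng,
        month=start_month,
        eligible=[h for h in survivors if group_of[h] == MOLTED],
    )
    for a in ages:
        if a != ages[1]:  # t23 is a control-only validation timepoint
            subsets[MOLTED][a] = molted_tracked

    # --- feature universe ----------------------------------------------
    width = max(4, len(str(config.n_features)))
    feature_ids = [f"F{i:0{width}d}" for i in range(1, config.n_features + 1)]
    chem_groups = [
        "amino acids", "organic acids", "sugars", "nucleotides", "TG", "PC",
        "PE", "ceramides", "fatty acids", "other",
    ]
    chemical_group = pd.Series(
        rng.choice(chem_groups, size=config.n_features), index=feature_ids, name="chemical_group"
    )
    log_scale = rng.uniform(2.0, 6.0, size=config.n_features) * np.log(10.0)

    n_aging = round(config.frac_aging_features * config.n_features)
    n_laying = round(config.frac_laying_features * config.n_features)
    aging_idx = rng.choice(config.n_features, size=n_aging, replace=False)
    laying_idx = rng.choice(config.n_features, size=n_laying, replace=False)
    direction = rng.choice([-1, 1], size=config.n_features)
    laying_sign_arr = rng.choice([-1, 1], size=config.n_features)
    aging_mask = np.zeros(config.n_features, dtype=bool)
    aging_mask[aging_idx] = True
    laying_mask = np.zeros(config.n_features, dtype=bool)
    laying_mask[laying_idx] = True
    # features planted as both aging and fecundity-linked get consistent
    # signs: more-with-age markers are less-with-efficiency and vice versa
    both = aging_mask & laying_mask
    laying_sign_arr[both] = -direction[both]

    sigma_base = float(np.sqrt(np.log1p(config.cv_base**2)))

    # group-age mean fecundity over living hens (reference for deviations)
    mean_fec = {
        g: {
            m: float(
                np.mean(
                    [
                        fecundity[h][m]
                        for h in hens
                        if group_of[h] == g and death_day.get(h, last_day + 1) > month_starts[m]
                    ]
                )
            )
            for m in months
        }
        for g in (CONTROL, MOLTED)
    }

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    for group in (CONTROL, MOLTED):
        for a in ages:
            if a not in subsets[group]:
                continue
            cv = planted_cv(config, group, a)
            sigma = float(np.sqrt(np.log1p(cv**2)))
            attn = (
                config.molt_attenuation if (group == MOLTED and a > start_month) else 1.0
            )
            shift = (
                direction
                * aging_mask
                * config.aging_effect_size
                * sigma_base
                * attn
                * (a - start_month)
                / 12.0
            )
            for h in subsets[group][a]:
                dev = fecundity[h][a] - mean_fec[group][a]
                lay = laying_sign_arr * laying_mask * config.laying_effect_size * dev
                log_int = log_scale + shift + lay + rng.normal(0.0, sigma, config.n_features)
                sid = f"{h}_t{a}"
                samples.append(SampleMeta(sid, h, group, a, a))
                columns[sid] = np.exp(log_int)

    intensities = pd.DataFrame(columns, index=feature_ids)
    if config.dropout_rate > 0:
        keep = rng.random(intensities.shape) >= config.dropout_rate
        intensities = intensities.where(keep, np.nan)
    table = MetaboliteTable(intensities, samples, chemical_group)

    # --- cytokine panel -------------------------------------------------
    cyto_base = np.exp(rng.normal(np.log(100.0), 1.0, size=N_CYTOKINES))
    cyto_sigma = float(np.sqrt(np.log1p(0.25**2)))
    rows = []
    for a in CYTOKINE_AGES:
        for h in hens:
            if death_day.get(h, last_day + 1) <= month_starts[a]:
                continue
            attn = config.molt_attenuation if group_of[h] == MOLTED else 1.0
            mean = cyto_base * np.exp(
                -config.cytokine_decline_per_year * attn * (a - start_month) / 12.0
            )
            vals = mean * np.exp(rng.normal(0.0, cyto_sigma, N_CYTOKINES))
            for c in range(N_CYTOKINES):
                rows.append(
                    {
                        "hen_id": h,
                        "group": group_of[h],
                        "age_months": a,
                        "channel": f"CYT{c + 1}",
                        "value": vals[c],
                    }
                )
    cytokines = pd.DataFrame(rows)

    month_of = lambda d: next(m for m in reversed(months) if month_starts[m] <= d)  # noqa: E731
    truth = SimTruth(
        aging_direction={feature_ids[i]: int(direction[i]) for i in sorted(aging_idx)},
        laying_sign={feature_ids[i]: int(laying_sign_arr[i]) for i in sorted(laying_idx)},
        fecundity=fecundity,
        sterility_onset_month={h: month_of(d) for h, d in sterility_onset_day.items()},
        death_month={h: month_of(d) for h, d in death_day.items()},
        metabolomics_subsets=subsets,
        planted_cv={
            g: {a: planted_cv(config, g, a) for a in ages} for g in (CONTROL, MOLTED)
        },
        molt_attenuation=config.molt_attenuation,
    )
    return table, log, cytokines, truth
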