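"""Reproduction and survival phenotypes derived from daily laying logs.

Laying efficiency is eggs laid over days in the period, per hen per month.
Sterility is 21 consecutive zero-egg days while alive (three weeks without
egg production, the finest reading the daily log supports); in laying hens
such a stretch is not recovered from under standard conditions and is
treated as a frailty indicator feeding the sterility-vs-mortality
contingency analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LayingLog

__all__ = [
    "EfficiencyRecord",
    "SurvivalRecord",
    "laying_efficiency",
    "efficiency_table",
    "cohort_median_efficiency",
    "detect_sterility",
    "survival_records",
    "mortality_fraction",
    "sterility_mortality_table",
]

#: consecutive zero-egg days that define sterility (three weeks)
STERILITY_WINDOW_DAYS = 21


@dataclass(frozen=True)
class EfficiencyRecord:
    hen_id: str
    month: int
    n_eggs: int
    n_days: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_eggs <= self.n_days):
            raise ValueError("eggs must lie in [0, days]")

    @property
    def efficiency(self) -> float:
        return self.n_eggs / self.n_days


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-hen monthly survival plus sterility onset (if any)."""

    hen_id: str
    alive_by_month: dict[int, bool]
    sterile_onset_month: int | None = None

    def __post_init__(self) -> None:
        # once dead, stays dead
        seen_dead = False
        for m in sorted(self.alive_by_month):
            if seen_dead and self.alive_by_month[m]:
                raise ValueError(f"hen {self.hen_id}: resurrection at month {m}")
            seen_dead = seen_dead or not self.alive_by_month[m]

    @property
    def died(self) -> bool:
        return not all(self.alive_by_month.values())

    @property
    def sterile(self) -> bool:
        return self.sterile_onset_month is not None


def laying_efficiency(
    log: LayingLog, hen_id: str, month: int, alive_days_denominator: bool = True
) -> EfficiencyRecord:
    """Monthly laying efficiency: eggs in the month / days in the month.

    Hens dying mid-month contribute only over days alive (denominator =
    days alive in the month) under the default; set
    ``alive_days_denominator=False`` to divide by the full month length.
    A hen dead for the entire month is an error.
    """
    start, end = log.month_span(month)
    days = log.hen_days(hen_id)
    in_month = days[(days["day"] >= start) & (days["day"] <= end)]
    if in_month.empty:
        raise ValueError(f"hen {hen_id} has no alive days in month {month}")
    n_days = len(in_month) if alive_days_denominator else (end - start + 1)
    return EfficiencyRecord(hen_id, month, int(in_month["egg"].sum()), n_days)


def efficiency_table(log: LayingLog, months: list[int] | None = None) -> pd.DataFrame:
    """Long-form efficiency records for every hen-month with alive days.

    Columns: hen_id, group, month, n_eggs, n_days, efficiency.
    """
    months = months if months is not None else log.months()
    rows = []
    for hen in log.hen_ids:
        for month in months:
            try:
                rec = laying_efficiency(log, hen, month)
            except ValueError:
                continue
            rows.append(
                {
                    "hen_id": hen,
                    "group": log.group_of.get(hen, ""),
                    "month": month,
                    "n_eggs": rec.n_eggs,
                    "n_days": rec.n_days,
                    "efficiency": rec.efficiency,
                }
            )
    return pd.DataFrame(rows)


def cohort_median_efficiency(log: LayingLog, hen_ids: list[str], month: int) -> float:
    """Median-then-divide cohort efficiency.

    The median of the per-hen monthly egg counts is computed first, then
    divided by the days in the month (the stated order; identical to the
    median of per-hen efficiencies when all hens share the month length).
    Dead hens contribute their (zero-padded) count only over alive days —
    hens with no alive days in the month are excluded.
    """
    start, end = log.month_span(month)
    counts = []
    for hen in hen_ids:
        days = log.hen_days(hen)
        in_month = days[(days["day"] >= start) & (days["day"] <= end)]
        if in_month.empty:
            continue
        counts.append(int(in_month["egg"].sum()))
    if not counts:
        raise ValueError(f"no living hens in month {month}")
    return float(np.median(counts)) / (end - start + 1)


def detect_sterility(
    log: LayingLog, hen_id: str, window: int = STERILITY_WINDOW_DAYS
) -> int | None:
    """Earliest day opening ``window`` consecutive zero-egg alive days.

    Returns the first day d such that days d..d+window−1 are all recorded
    (hen alive) with zero eggs, or None when no such stretch exists.  Any
    egg inside a candidate window restarts the count.
    """
    days = log.hen_days(hen_id)
    day_idx = days["day"].to_numpy()
    eggs = days["egg"].to_numpy()
    run = 0
    for i in range(len(day_idx)):
        contiguous = i > 0 and day_idx[i] == day_idx[i - 1] + 1
        run = run + 1 if (eggs[i] == 0 and (run == 0 or contiguous)) else (1 if eggs[i] == 0 else 0)
        if run >= window:
            return int(day_idx[i] - window + 1)
    return None


def _month_of_day(log: LayingLog, day: int) -> int:
    months = sorted(log.month_starts)
    for m in reversed(months):
        if day >= log.month_starts[m]:
            return m
    return months[0]


def survival_records(log: LayingLog) -> list[SurvivalRecord]:
    """Build per-hen survival + sterility records from a laying log."""
    months = log.months()
    records = []
    for hen in log.hen_ids:
        death = log.death_day.get(hen)
        alive = {
            m: (death is None or death > log.month_span(m)[1]) for m in months
        }
        onset_day = detect_sterility(log, hen)
        onset_month = _month_of_day(log, onset_day) if onset_day is not None else None
        records.append(SurvivalRecord(hen, alive, onset_month))
    return records


def mortality_fraction(survival: list[SurvivalRecord]) -> tuple[int, float]:
    """Cohort mortality as (nearest-integer percent, raw fraction).

    100 · deaths / initial cohort size; the integer percent matches the
    field's reporting convention, the raw fraction is kept alongside.
    """
    if not survival:
        raise ValueError("empty cohort")
    deaths = sum(r.died for r in survival)
    frac = deaths / len(survival)
    return int(round(100 * frac)), frac


def sterility_mortality_table(survival: list[SurvivalRecord]) -> np.ndarray:
    """2×2 counts [[sterile∧died, sterile∧survived],
    [non-sterile∧died, non-sterile∧survived]] for Fisher's exact test."""
    t = np.zeros((2, 2), dtype=int)
    for r in survival:
        t[0 if r.sterile else 1, 0 if r.died else 1] += 1
    return t
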