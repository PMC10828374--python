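"""In-memory containers for cohort data and their plain-text interfaces.

A :class:`MetaboliteTable` holds a positive feature-by-sample intensity
matrix (abstract LC–MS intensities spanning orders of magnitude) together
with per-sample metadata and per-feature chemical-group labels.  A
:class:`LayingLog` holds the daily egg record per hen plus death days and
month boundaries.  Both round-trip through uncompressed TSV/CSV so pipeline
stages can run on user-supplied real tables as well as simulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SampleMeta", "MetaboliteTable", "LayingLog"]

CONTROL = "control"
MOLTED = "molted"
GROUPS = (CONTROL, MOLTED)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one metabolomics sample (one hen at one timepoint)."""

    sample_id: str
    hen_id: str
    group: str
    age_months: int
    sampling_month: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class MetaboliteTable:
    """Positive intensity matrix (features × samples) with metadata.

    ``intensities`` is a DataFrame indexed by feature id with one column
    per sample id; ``samples`` carries one :class:`SampleMeta` per column,
    in column order; ``chemical_group`` maps feature id → label.
    """

    intensities: pd.DataFrame
    samples: list[SampleMeta]
    chemical_group: pd.Series

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if list(self.intensities.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("sample metadata must match matrix columns in order")
        if not (self.intensities.to_numpy() > 0).all():
            raise ValueError("all intensities must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample id."""
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "hen_id": s.hen_id,
                    "group": s.group,
                    "age_months": s.age_months,
                    "sampling_month": s.sampling_month,
                }
                for s in self.samples
            ]
        ).set_index("sample_id")

    def subset(self, group: str | None = None, ages: list[int] | None = None) -> "MetaboliteTable":
        """Restrict to samples of one group and/or a set of ages."""
        keep = [
            s
            for s in self.samples
            if (group is None or s.group == group)
            and (ages is None or s.age_months in ages)
        ]
        ids = [s.sample_id for s in keep]
        return MetaboliteTable(self.intensities[ids], keep, self.chemical_group)

    def values_for(self, group: str, age: int) -> pd.DataFrame:
        """Intensity submatrix for one (group, age) cell."""
        return self.subset(group=group, ages=[age]).intensities

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        out = self.intensities.copy()
        out.insert(0, "chemical_group", self.chemical_group.reindex(out.index))
        out.to_csv(matrix_path, sep="\t", index_label="feature_id")
        self.sample_frame.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, meta_path: str | Path) -> "MetaboliteTable":
        mat = pd.read_csv(matrix_path, sep="\t", index_col="feature_id")
        groups = mat.pop("chemical_group")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        samples = [
            SampleMeta(
                sample_id=str(sid),
                hen_id=str(row["hen_id"]),
                group=str(row["group"]),
                age_months=int(row["age_months"]),
                sampling_month=int(row["sampling_month"]),
            )
            for sid, row in meta.iterrows()
        ]
        mat = mat[[s.sample_id for s in samples]]
        return cls(mat, samples, groups)


@dataclass
class LayingLog:
    """Daily egg record for a cohort.

    ``eggs`` is a long-form DataFrame with columns (hen_id, day, egg) where
    day 0 is the first day of the study (hen age = first month boundary)
    and egg ∈ {0, 1}; rows exist only for days a hen is alive.
    ``death_day`` maps hen id → day of death (absent = survived).
    ``month_starts`` maps age-in-months → first study day of that month;
    consecutive boundaries are 28–31 days apart.
    """

    eggs: pd.DataFrame
    death_day: dict[str, int] = field(default_factory=dict)
    month_starts: dict[int, int] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        months = sorted(self.month_starts)
        for a, b in zip(months, months[1:]):
            d = self.month_starts[b] - self.month_starts[a]
            if not (28 <= d <= 31):
                raise ValueError(f"month {a}: {d} days outside [28, 31]")

    @property
    def hen_ids(self) -> list[str]:
        return sorted(self.eggs["hen_id"].unique())

    def months(self) -> list[int]:
        """Age months fully covered by the log (a following boundary exists)."""
        months = sorted(self.month_starts)
        return months[:-1]

    def month_span(self, month: int) -> tuple[int, int]:
        """(first day, last day inclusive) of an age month."""
        months = sorted(self.month_starts)
        if month not in self.month_starts or month == months[-1]:
            raise KeyError(f"month {month} not fully covered by the log")
        start = self.month_starts[month]
        end = self.month_starts[months[months.index(month) + 1]] - 1
        return start, end

    def days_in_month(self, month: int) -> int:
        start, end = self.month_span(month)
        return end - start + 1

    def hen_days(self, hen_id: str) -> pd.DataFrame:
        sub = self.eggs[self.eggs["hen_id"] == hen_id]
        if sub.empty:
            raise KeyError(f"unknown hen {hen_id!r}")
        return sub.sort_values("day")

    def to_csv(self, path: str | Path) -> None:
        self.eggs.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        month_starts: dict[int, int],
        death_day: dict[str, int] | None = None,
        group_of: dict[str, str] | None = None,
    ) -> "LayingLog":
        eggs = pd.read_csv(path, dtype={"hen_id": str})
        return cls(eggs, death_day or {}, month_starts, group_of or {})


def month_boundaries(start_month: int, n_months: int) -> dict[int, int]:
    """Calendar-like month boundaries (repeating 31/30-day pattern).

    All hens share a hatching date, so months are indexed by hen age.  The
    exact day counts are a convention; they stay within [28, 31].
    """
    pattern = [31, 30, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    starts = {start_month: 0}
    day = 0
    for i in range(n_months):
        day += pattern[(start_month + i) % 12]
        starts[start_month + i + 1] = day
    return starts
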