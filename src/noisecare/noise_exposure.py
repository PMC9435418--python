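"""Occupational noise dosimetry: energetic averaging and daily exposure.

Implements the ISO 9612 quantities used throughout the pipeline: the
logarithmic (energetic) mean of repeated one-minute Leq readings at a
measurement point, a worker's A-weighted equivalent level over the effective
shift ``LAeq,Te`` from workstation contributions, and the daily personal
noise exposure level ``LEP,d`` referenced to T0 = 8 h.

All decibel arithmetic happens in the power domain; nothing is rounded until
presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LeqSeries",
    "WorkstationContribution",
    "ExposureResult",
    "log_mean",
    "personal_daily_exposure",
    "categorize_exposure",
    "build_noise_map",
    "personal_exposures",
    "EXPOSURE_CATEGORIES",
]

#: ordered exposure categories; boundaries are closed on [50, 60] for moderate
EXPOSURE_CATEGORIES = ("low", "moderate", "high")
LOW_UPPER_DB = 50.0
HIGH_LOWER_DB = 60.0
T0_HOURS = 8.0


@dataclass(frozen=True)
class LeqSeries:
    """Repeated one-minute Leq readings at one measurement point."""

    point_id: str
    levels_db: tuple[float, ...]
    department: str = ""
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels_db", tuple(float(v) for v in self.levels_db))
        if not self.levels_db:
            raise ValueError(f"point {self.point_id!r}: no Leq readings")
        if not all(math.isfinite(v) for v in self.levels_db):
            raise ValueError(f"point {self.point_id!r}: non-finite Leq reading")


@dataclass(frozen=True)
class WorkstationContribution:
    """One task: the workstation's LAeq and the time spent there."""

    level_db: float
    duration_h: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.level_db):
            raise ValueError("workstation level must be finite")
        if not self.duration_h > 0:
            raise ValueError("task duration must be positive")


@dataclass(frozen=True)
class ExposureResult:
    laeq_te_db: float
    lep_d_db: float
    category: str


def log_mean(levels_db: Sequence[float]) -> float:
    """Energetic mean 10*log10(mean(10^(Li/10))) of sound levels in dB."""
    levels = np.asarray(list(levels_db), dtype=float)
    if levels.size == 0:
        raise ValueError("log_mean of an empty list")
    if not np.all(np.isfinite(levels)):
        raise ValueError("log_mean requires finite levels")
    return float(10.0 * np.log10(np.mean(10.0 ** (levels / 10.0))))


def categorize_exposure(lep_d_db: float) -> str:
    """low below 50 dBA, moderate on [50, 60], high above 60."""
    if not math.isfinite(lep_d_db):
        raise ValueError("exposure level must be finite")
    if lep_d_db < LOW_UPPER_DB:
        return "low"
    if lep_d_db <= HIGH_LOWER_DB:
        return "moderate"
    return "high"


def personal_daily_exposure(
    contributions: Iterable[WorkstationContribution],
    t0_h: float = T0_HOURS,
) -> ExposureResult:
    """LAeq over the effective duration Te and LEP,d referenced to ``t0_h``.

    LAeq,Te = 10*log10(sum_i (ti/Te) * 10^(Li/10));
    LEP,d = LAeq,Te + 10*log10(Te/T0).
    """
    contributions = list(contributions)
    if not contributions:
        raise ValueError("at least one workstation contribution is required")
    te = sum(c.duration_h for c in contributions)
    power = sum(
        (c.duration_h / te) * 10.0 ** (c.level_db / 10.0) for c in contributions
    )
    laeq = 10.0 * math.log10(power)
    lep_d = laeq + 10.0 * math.log10(te / t0_h)
    return ExposureResult(laeq, lep_d, categorize_exposure(lep_d))


def build_noise_map(grid: pd.DataFrame | Iterable[LeqSeries]) -> pd.DataFrame:
    """Collapse repeated readings to one energetic mean per point.

    Accepts either a tidy frame with columns ``point_id``, ``department``,
    ``leq_db`` (optionally ``x``, ``y``, ``repeat_index``) or an iterable of
    :class:`LeqSeries`.  Returns one row per point with ``mapped_level_db``.
    """
    if not isinstance(grid, pd.DataFrame):
        series = list(grid)
        grid = pd.DataFrame(
            {
                "point_id": np.repeat(
                    [s.point_id for s in series],
                    [len(s.levels_db) for s in series],
                ),
                "department": np.repeat(
                    [s.department for s in series],
                    [len(s.levels_db) for s in series],
                ),
                "x": np.repeat(
                    [np.nan if s.x is None else s.x for s in series],
                    [len(s.levels_db) for s in series],
                ),
                "y": np.repeat(
                    [np.nan if s.y is None else s.y for s in series],
                    [len(s.levels_db) for s in series],
                ),
                "leq_db": np.concatenate([s.levels_db for s in series])
                if series
                else np.array([]),
            }
        )
    required = {"point_id", "leq_db"}
    if not required.issubset(grid.columns):
        raise ValueError(f"noise grid needs columns {sorted(required)}")
    meta_cols = [c for c in ("department", "x", "y") if c in grid.columns]
    meta = grid[["point_id", *meta_cols]].drop_duplicates()
    dupes = meta["point_id"][meta["point_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            "conflicting department/coordinates for point(s): "
            f"{sorted(set(dupes))[:5]}"
        )
    mapped = (
        grid.groupby("point_id", sort=False)["leq_db"]
        .apply(lambda v: log_mean(v.to_numpy()))
        .rename("mapped_level_db")
        .reset_index()
    )
    return mapped.merge(meta, on="point_id")[
        ["point_id", *meta_cols, "mapped_level_db"]
    ]


def personal_exposures(
    grid: pd.DataFrame | Iterable[LeqSeries],
    stations: pd.DataFrame,
    t0_h: float = T0_HOURS,
) -> pd.DataFrame:
    """Per-nurse LAeq,Te, LEP,d and category from a grid and assignments.

    ``stations`` needs columns ``nurse_id``, ``point_id``, ``duration_h``;
    each workstation's level is the energetic mean of its grid repeats.
    """
    noise_map = build_noise_map(grid)
    need = {"nurse_id", "point_id", "duration_h"}
    if not need.issubset(stations.columns):
        raise ValueError(f"stations table needs columns {sorted(need)}")
    merged = stations.merge(
        noise_map[["point_id", "mapped_level_db"]], on="point_id", how="left"
    )
    if merged["mapped_level_db"].isna().any():
        bad = sorted(set(merged.loc[merged["mapped_level_db"].isna(), "point_id"]))
        raise ValueError(f"workstation point(s) absent from grid: {bad[:5]}")
    rows = []
    for nurse_id, grp in merged.groupby("nurse_id", sort=False):
        contribs = [
            WorkstationContribution(lv, d)
            for lv, d in zip(grp["mapped_level_db"], grp["duration_h"])
        ]
        res = personal_daily_exposure(contribs, t0_h=t0_h)
        rows.append((nurse_id, res.laeq_te_db, res.lep_d_db, res.category))
    return pd.DataFrame(
        rows, columns=["nurse_id", "laeq_te_db", "lep_d_db", "exposure"]
    )
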