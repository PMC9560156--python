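"""Cell-culture growth analytics: percent change, cumulative population
doubling level (PDL), and average doubling time.

A long-term culture is recorded as passages: on each interval a known
number of cells is seeded and the harvest is counted before re-seeding.
The PDL increment of a passage is log2(harvested/seeded) — negative when
the culture declines — and the cumulative PDL at each passage end is
their running sum.  The average doubling time over a window is the
elapsed days divided by the PDL gained, which weights every day equally
regardless of how the window was cut into passages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PassageSeries",
    "DoublingSummary",
    "percent_change",
    "cumulative_pdl",
    "average_doubling_time",
    "replicate_doubling_time",
]

PASSAGE_COLUMNS = ("start_day", "end_day", "seeded", "harvested")
COUNT_COLUMNS = ("condition", "replicate", "day", "cells", "kind")


@dataclass(frozen=True)
class PassageSeries:
    """Ordered, contiguous passages for one culture (one replicate).

    ``passages`` is a DataFrame with columns start_day, end_day, seeded,
    harvested; intervals must be increasing, non-overlapping and
    contiguous, with positive counts.
    """

    passages: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.passages
        missing = set(PASSAGE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"passage table missing columns {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("passage table is empty")
        if (df["end_day"] <= df["start_day"]).any():
            raise ValueError("each passage needs end_day > start_day")
        if (df["seeded"] <= 0).any() or (df["harvested"] <= 0).any():
            raise ValueError("seeded and harvested counts must be positive")
        starts = df["start_day"].to_numpy()
        ends = df["end_day"].to_numpy()
        if not np.allclose(starts[1:], ends[:-1]):
            raise ValueError("passages must be contiguous and non-overlapping")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PassageSeries":
        return cls(df.sort_values("start_day").reset_index(drop=True))

    @property
    def start_day(self) -> float:
        return float(self.passages["start_day"].iloc[0])

    @property
    def end_day(self) -> float:
        return float(self.passages["end_day"].iloc[-1])


def percent_change(
    records: pd.DataFrame, condition: str, day_a: float, day_b: float
) -> float:
    """Signed percent change in mean cell number between two days.

    Replicates are averaged before the ratio, mirroring how growth-curve
    panels report a single mean trace with error bars.
    """
    sub = records[records["condition"] == condition]
    mean_a = sub.loc[np.isclose(sub["day"], day_a), "cells"].mean()
    mean_b = sub.loc[np.isclose(sub["day"], day_b), "cells"].mean()
    if math.isnan(mean_a) or math.isnan(mean_b):
        raise ValueError(
            f"condition {condition!r} lacks counts on day {day_a} or {day_b}"
        )
    if mean_a <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (mean_b - mean_a) / mean_a


def cumulative_pdl(series: PassageSeries) -> pd.DataFrame:
    """Per-passage PDL increments and their cumulative sum.

    Returns a DataFrame with columns end_day, pdl_increment and
    cumulative_pdl; increments may be negative for declining cultures.
    """
    df = series.passages
    increments = np.log2(df["harvested"].to_numpy() / df["seeded"].to_numpy())
    return pd.DataFrame(
        {
            "end_day": df["end_day"].to_numpy(),
            "pdl_increment": increments,
            "cumulative_pdl": np.cumsum(increments),
        }
    )


@dataclass(frozen=True)
class DoublingSummary:
    """Average doubling time over a window of a passage series.

    ``days_per_doubling`` is None (undefined) when the culture gained no
    doublings — a declining culture has no meaningful doubling time.
    """

    total_days: float
    total_pdl: float
    days_per_doubling: float | None
    window: tuple[float, float]

    @property
    def defined(self) -> bool:
        return self.days_per_doubling is not None


def average_doubling_time(
    series: PassageSeries,
    window: tuple[float, float] | None = None,
    estimator: str = "cumulative",
) -> DoublingSummary:
    """Average days per population doubling over a day window.

    ``estimator="cumulative"`` (default) divides total elapsed days by
    total PDL gained — every day weighted equally.  The alternative
    ``"per_passage"`` averages each passage's own days-per-doubling,
    which overweights short passages and is provided for comparison
    only.  The window must align with passage boundaries and contain at
    least one complete passage.
    """
    df = series.passages
    if window is None:
        window = (series.start_day, series.end_day)
    lo, hi = window
    inside = df[(df["start_day"] >= lo - 1e-9) & (df["end_day"] <= hi + 1e-9)]
    if len(inside) == 0:
        raise ValueError(f"window {window} contains no complete passage")
    increments = np.log2(inside["harvested"].to_numpy() / inside["seeded"].to_numpy())
    total_days = float(inside["end_day"].iloc[-1] - inside["start_day"].iloc[0])
    total_pdl = float(increments.sum())
    if estimator == "cumulative":
        dpd = total_days / total_pdl if total_pdl > 0 else None
    elif estimator == "per_passage":
        spans = (inside["end_day"] - inside["start_day"]).to_numpy()
        if (increments <= 0).any():
            dpd = None
        else:
            dpd = float(np.mean(spans / increments))
    else:
        raise ValueError("estimator must be 'cumulative' or 'per_passage'")
    return DoublingSummary(
        total_days=total_days,
        total_pdl=total_pdl,
        days_per_doubling=dpd,
        window=(float(inside["start_day"].iloc[0]), float(inside["end_day"].iloc[-1])),
    )


def replicate_doubling_time(
    passages: pd.DataFrame,
    window: tuple[float, float] | None = None,
    estimator: str = "cumulative",
) -> DoublingSummary:
    """Doubling summary for a multi-replicate passage table.

    Each replicate's cumulative PDL is computed separately and the
    replicate PDLs are averaged before dividing into elapsed days, so a
    noisy replicate contributes its doublings, not its ratio.
    """
    if "replicate" not in passages.columns:
        return average_doubling_time(
            PassageSeries.from_frame(passages), window, estimator
        )
    summaries = [
        average_doubling_time(PassageSeries.from_frame(grp), window, estimator)
        for _, grp in passages.groupby("replicate")
    ]
    total_days = summaries[0].total_days
    mean_pdl = float(np.mean([s.total_pdl for s in summaries]))
    dpd = total_days / mean_pdl if mean_pdl > 0 else None
    return DoublingSummary(
        total_days=total_days,
        total_pdl=mean_pdl,
        days_per_doubling=dpd,
        window=summaries[0].window,
    )
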