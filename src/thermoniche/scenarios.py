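"""Thermal occupancy scenario construction.

Two annual temperature cycles drive every comparison:

* the **observed** scenario — the realized thermal niche, built from daily
  temperatures of tagged individuals: individual daily means, then the
  across-individual mean per date, then the day-of-year climatology pooled
  across years, averaged at thirteen 30-day nodes (±10-day windows) anchored
  at the species' simulation start date, then linearly interpolated back to
  365 days; and
* the **assumed** scenario — the lab physiological optimum, capped by what
  the habitat offers: node-wise min(optimum, warmest available temperature).

The year is 365 days; leap days are dropped.  Node windows wrap circularly
around the year because the annual cycle is presumed to repeat.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ScenarioGapError

#: 1-based simulation days of the 13 scenario nodes: 1, 31, ..., 361.
NODE_DAYS = tuple(1 + 30 * k for k in range(13))


def day_of_year(date: dt.date) -> int | None:
    """Day-of-year on a 365-day calendar; Feb 29 maps to None (dropped)."""
    doy = date.timetuple().tm_yday
    if date.month == 2 and date.day == 29:
        return None
    leap = date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)
    if leap and doy > 59:  # after Feb 29
        doy -= 1
    return doy


def start_doy(start: tuple[int, int]) -> int:
    """Calendar day-of-year of a (month, day) start on the 365-day calendar."""
    return dt.date(2001, start[0], start[1]).timetuple().tm_yday


def sim_day_to_doy(sim_day: int, start: tuple[int, int]) -> int:
    """Map simulation day (1..365) to calendar day-of-year, wrapping."""
    return (start_doy(start) - 1 + sim_day - 1) % 365 + 1


@dataclass(frozen=True)
class TagTemperatureSet:
    """Daily temperature records of tagged individuals.

    ``records`` has columns ``individual_id``, ``date`` (datetime-like) and
    ``temp_C``; temperatures must be plausible for a temperate lake.
    """

    records: pd.DataFrame
    species: str = ""

    def __post_init__(self) -> None:
        required = {"individual_id", "date", "temp_C"}
        missing = required - set(self.records.columns)
        if missing:
            raise DomainError(f"tag records missing columns: {sorted(missing)}")
        t = self.records["temp_C"]
        if len(t) == 0:
            raise DomainError("tag record set is empty")
        bad = (t < -1.0) | (t > 35.0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DomainError(
                f"temperature {t.iloc[i]} degC at row {i} outside plausible "
                "lake range [-1, 35]"
            )


def daily_species_means(tags: TagTemperatureSet) -> pd.Series:
    """Day-of-year climatology of species-occupied temperature.

    Averaging order: per-individual daily mean -> across-individual mean per
    calendar date -> across-year mean per day-of-year.  The two-stage rule
    keeps individuals with many readings from dominating a day.  Returns a
    Series indexed by day-of-year (1..365); days without data are absent.
    """
    df = tags.records.copy()
    if len(df) == 0:
        raise DomainError("cannot average an empty tag set")
    dates = pd.to_datetime(df["date"])
    df["date"] = dates.dt.date
    per_ind_day = df.groupby(["individual_id", "date"])["temp_C"].mean()
    per_date = per_ind_day.groupby(level="date").mean()
    doys = per_date.index.map(day_of_year)
    keep = pd.notna(doys)
    per_date = per_date[keep]
    out = per_date.groupby(doys[keep].astype(int)).mean()
    out.index.name = "doy"
    return out


def nodes_from_daily(
    daily: Mapping[int, float] | pd.Series,
    start: tuple[int, int],
    window: int = 10,
) -> np.ndarray:
    """Thirteen node temperatures at 30-day spacing on the simulation-day axis.

    Node k sits at simulation day 1 + 30k; its value is the mean of the
    available daily values within ±``window`` days of the mark, wrapping
    around the 365-day year.  An empty window raises a gap error naming the
    node.
    """
    series = pd.Series(dict(daily)) if not isinstance(daily, pd.Series) else daily
    lut = {int(k): float(v) for k, v in series.items()}
    nodes = np.empty(13)
    for k, mark in enumerate(NODE_DAYS):
        vals = []
        for off in range(-window, window + 1):
            doy = sim_day_to_doy(mark + off, start)
            if doy in lut:
                vals.append(lut[doy])
        if not vals:
            raise ScenarioGapError(
                f"node {k} (simulation day {mark}): no daily temperatures "
                f"within +/-{window} days"
            )
        nodes[k] = float(np.mean(vals))
    return nodes


def interpolate(nodes: Sequence[float]) -> np.ndarray:
    """Linear interpolation of 13 nodes to a 365-day cycle.

    Nodes sit at days 1, 31, ..., 361; beyond day 361 the series runs
    linearly to node 0 of the repeated cycle at (virtual) day 366, keeping
    the wrap continuous.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.shape != (13,):
        raise DomainError(f"need exactly 13 nodes, got {nodes.shape}")
    xp = np.array(list(NODE_DAYS) + [366], dtype=float)
    fp = np.concatenate([nodes, nodes[:1]])
    return np.interp(np.arange(1, 366, dtype=float), xp, fp)


@dataclass(frozen=True)
class TemperatureScenario:
    """A 13-node annual temperature cycle plus its daily interpolation."""

    label: str
    start: tuple[int, int]
    nodes: np.ndarray
    daily: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.nodes).shape != (13,):
            raise DomainError("scenario must have 13 nodes")
        if np.asarray(self.daily).shape != (365,):
            raise DomainError("scenario must have 365 daily values")

    @classmethod
    def from_nodes(
        cls, label: str, start: tuple[int, int], nodes: Sequence[float]
    ) -> "TemperatureScenario":
        nodes = np.asarray(nodes, dtype=float)
        return cls(label=label, start=start, nodes=nodes, daily=interpolate(nodes))

    @classmethod
    def from_tags(
        cls,
        tags: TagTemperatureSet,
        start: tuple[int, int],
        label: str = "observed",
        window: int = 10,
    ) -> "TemperatureScenario":
        daily = daily_species_means(tags)
        nodes = nodes_from_daily(daily, start, window=window)
        return cls.from_nodes(label, start, nodes)

    def to_dataframe(self) -> pd.DataFrame:
        node_flag = np.zeros(365, dtype=int)
        node_flag[np.array(NODE_DAYS) - 1] = 1
        return pd.DataFrame(
            {"sim_day": np.arange(1, 366), "node_flag": node_flag, "temp_C": self.daily}
        )


def build_assumed(
    optimum: float,
    warmest_available: Sequence[float],
    start: tuple[int, int],
    label: str = "assumed",
) -> TemperatureScenario:
    """Assumed thermal occupancy: the physiological optimum, or the warmest
    available temperature when the optimum is seasonally unavailable —
    node-wise min(optimum, warmest available)."""
    wa = np.asarray(warmest_available, dtype=float)
    if wa.shape != (13,):
        raise DomainError(f"warmest_available must have 13 values, got {wa.shape}")
    return TemperatureScenario.from_nodes(label, start, np.minimum(optimum, wa))
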