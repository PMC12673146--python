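"""Seasonal labelling, station summaries and risk-category distributions.

The catchment has a bimodal rainfall calendar: the dry season covers
January–February and June–August, the wet season March–May and
September–December.  Seasonal index comparisons use the two-sided
Wilcoxon rank-sum (Mann–Whitney U) test on the pooled station-month
samples of each season.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .records import MonitoringRecord
from .risk import RISK_LEVELS

__all__ = [
    "SeasonCalendar",
    "DEFAULT_CALENDAR",
    "StationSummary",
    "RiskDistribution",
    "season_of",
    "summarize_station",
    "seasonal_compare",
    "risk_distribution",
]

DRY, WET = "dry", "wet"


@dataclass(frozen=True)
class SeasonCalendar:
    """Total mapping of the twelve calendar months to {dry, wet}."""

    months: Mapping[int, str] = field(
        default_factory=lambda: {
            m: (DRY if m in (1, 2, 6, 7, 8) else WET) for m in range(1, 13)
        }
    )

    def __post_init__(self) -> None:
        if set(self.months) != set(range(1, 13)):
            raise ValueError("season calendar must label all 12 months")
        bad = {m: s for m, s in self.months.items() if s not in (DRY, WET)}
        if bad:
            raise ValueError(f"season labels must be 'dry' or 'wet': {bad}")


DEFAULT_CALENDAR = SeasonCalendar()


def season_of(month: int, calendar: SeasonCalendar | None = None) -> str:
    """Season label of a calendar month (1–12)."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return (calendar or DEFAULT_CALENDAR).months[int(month)]


@dataclass(frozen=True)
class StationSummary:
    station: str
    parameter: str
    n: int
    mean: float
    sd: float


def summarize_station(records: Sequence[MonitoringRecord],
                      parameter: str) -> StationSummary:
    """Mean ± sample standard deviation (n−1) of one parameter at one station."""
    values = [r.values[parameter] for r in records
              if parameter in r.values and not np.isnan(r.values[parameter])]
    if not values:
        raise ValueError(f"no {parameter} values in the supplied records")
    stations = {r.station for r in records}
    if len(stations) > 1:
        raise ValueError(f"records span several stations: {sorted(stations)}")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return StationSummary(station=next(iter(stations)), parameter=parameter,
                          n=arr.size, mean=float(arr.mean()), sd=sd)


def seasonal_compare(values_dry: Sequence[float],
                     values_wet: Sequence[float]) -> dict[str, float]:
    """Two-sided rank-sum comparison of two independent seasonal groups.

    Returns the Mann–Whitney U statistic (of the dry group) and its
    two-sided p-value.
    """
    dry = np.asarray(values_dry, dtype=float)
    wet = np.asarray(values_wet, dtype=float)
    if dry.size == 0 or wet.size == 0:
        raise ValueError("both seasonal groups must be non-empty")
    res = stats.mannwhitneyu(dry, wet, alternative="two-sided")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


def _round_percent(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class RiskDistribution:
    """Counts, raw fractions and one-decimal percentages per risk level.

    Percentages are re-derived from the counts with round-half-even at one
    decimal (5/16 → 31.2, 3/16 → 18.8), never accumulated; the raw fractions
    are kept alongside so any other printed rounding convention can be
    matched.
    """

    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    percentages: Mapping[str, float]
    n_stations: int


def risk_distribution(station_levels: Sequence[str]) -> RiskDistribution:
    """Distribution of stations across the five risk categories."""
    if not station_levels:
        raise ValueError("need at least one station risk level")
    unknown = set(station_levels) - set(RISK_LEVELS)
    if unknown:
        raise ValueError(f"unknown risk levels: {sorted(unknown)}")
    n = len(station_levels)
    counts = {lvl: station_levels.count(lvl) for lvl in RISK_LEVELS}
    fractions = {lvl: c / n for lvl, c in counts.items()}
    percentages = {lvl: _round_percent(100.0 * c / n) for lvl, c in counts.items()}
    return RiskDistribution(counts=counts, fractions=fractions,
                            percentages=percentages, n_stations=n)
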