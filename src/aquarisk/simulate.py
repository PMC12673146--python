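"""Synthetic monitoring-data generator.

Emulates the statistical shape of a year of monthly sampling in the Maziba
sub-catchment: 16 stations × 12 months (July 2023 – June 2024) × 19
physicochemical parameters, n = 192 station-month records.

Structure of the default scenario
---------------------------------
* Every station×parameter cell carries a target mean and standard
  deviation.  Cells for which station statistics are published (e.g.
  turbidity 82.38 ± 66.69 NTU at Maziba Dam M16, DO 4.31 ± 1.44 mg/L at
  Lower Bugongi M8) use those values verbatim; the remaining cells are
  interpolated log-linearly between the anchored extremes along a fixed
  per-station anthropogenic-pressure score (urban-influenced M8/M9 and
  intensively farmed M1 highest; north-western headwaters M3/M5/M6/M7 and
  M15 lowest).
* Seasonality enters as multiplicative dry/wet factors on the cell mean
  only: turbidity and suspended solids rise in the wet season (runoff)
  while conductivity and the major ions fall (dilution).
* Noise is lognormal with exact moment matching
  (μ = ln(m²/√(m²+s²)), σ² = ln(1+s²/m²)), because several published
  cells have SD ≥ mean (TSS at M16: 298.75 ± 343.81 mg/L) — impossible
  under a truncated normal without severe bias.  pH is drawn normal on
  its own scale and clipped to [5, 9].

Identical seeds give bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import MonitoringRecord
from .standards import default_standards

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "with_wet_cpi_multiplier",
    "generate",
    "generate_frame",
    "draw_cell",
    "DEFAULT_MONTHS",
    "PRESSURE",
]

DEFAULT_MONTHS = tuple(
    f"{y}-{m:02d}" for y, m in
    [(2023, m) for m in range(7, 13)] + [(2024, m) for m in range(1, 7)]
)

# Per-station anthropogenic pressure score in [0, 1], fixed from the
# catchment narrative: M8/M9 sit below the main urban discharge, M1 under
# intensive hillslope agriculture; sub-catchments of M3/M5/M6/M7 and M15
# are the cleaner headwaters.
PRESSURE: dict[str, float] = {
    "M1": 0.85, "M2": 0.60, "M3": 0.12, "M4": 0.50, "M5": 0.18, "M6": 0.05,
    "M7": 0.20, "M8": 0.95, "M9": 0.90, "M10": 0.60, "M11": 0.45, "M12": 0.70,
    "M13": 0.65, "M14": 0.55, "M15": 0.22, "M16": 0.75,
}

# Interpolation lines: parameter -> ((u_a, mean_a, cv_a), (u_b, mean_b, cv_b),
# scale).  Endpoints anchored to published station statistics where printed,
# chosen once otherwise.  "log" interpolates the mean geometrically in the
# pressure score u, "linear" arithmetically (pH only).
_LINES: dict[str, tuple[tuple[float, float, float], tuple[float, float, float], str]] = {
    "DO":    ((0.05, 6.91, 0.166), (0.95, 4.31, 0.334), "log"),
    "PH":    ((0.05, 7.30, 0.041), (0.95, 6.80, 0.035), "linear"),
    "TURB":  ((0.05, 17.44, 0.413), (0.75, 82.38, 0.810), "log"),
    "EC":    ((0.22, 73.50, 0.323), (0.65, 262.25, 0.286), "log"),
    "TDS":   ((0.22, 51.44, 0.323), (0.65, 172.28, 0.358), "log"),
    "TSS":   ((0.05, 52.42, 0.591), (0.75, 298.75, 1.151), "log"),
    "NO2_N": ((0.00, 0.02, 0.800), (1.00, 0.35, 0.800), "log"),
    "TP":    ((0.05, 0.16, 1.100), (0.75, 0.40, 1.300), "log"),
    "TN":    ((0.22, 2.95, 0.298), (0.90, 4.91, 0.177), "log"),
    "NA":    ((0.00, 4.00, 0.400), (1.00, 18.00, 0.400), "log"),
    "K":     ((0.00, 1.50, 0.400), (1.00, 7.00, 0.400), "log"),
    "CL":    ((0.00, 4.00, 0.450), (1.00, 30.00, 0.450), "log"),
    "SO4":   ((0.00, 2.00, 0.500), (1.00, 12.00, 0.500), "log"),
    "TH":    ((0.00, 25.00, 0.350), (1.00, 95.00, 0.350), "log"),
}

# Parameters that are not pressure-ordered get a flat default (mean, sd).
_FLAT: dict[str, tuple[float, float]] = {
    "WT": (20.0, 2.0),
    "CHL_A": (3.5, 1.3),
    "NO3_N": (2.6, 0.9),
    "SRP": (0.07, 0.05),
}

# Ammonium is dominated by localised point sources (urban discharge at
# M8/M9, intensive agriculture at M1) rather than a smooth catchment
# gradient, so it gets explicit per-station means: low in the headwaters,
# a middle band elsewhere, sharp peaks at the three impacted stations.
# The published extremes (M6 and M1) override with printed mean and SD;
# the rest take SD = 0.65 × mean.
_NH4_MEANS: dict[str, float] = {
    "M1": 0.41, "M2": 0.16, "M3": 0.075, "M4": 0.14, "M5": 0.08, "M6": 0.07,
    "M7": 0.085, "M8": 0.35, "M9": 0.38, "M10": 0.16, "M11": 0.13,
    "M12": 0.18, "M13": 0.17, "M14": 0.15, "M15": 0.09, "M16": 0.19,
}

# Published station anchors overriding the interpolated table verbatim:
# (station, parameter) -> (mean, sd).
ANCHORS: dict[tuple[str, str], tuple[float, float]] = {
    ("M12", "WT"): (22.15, 2.65), ("M13", "WT"): (18.27, 1.43),
    ("M6", "TURB"): (17.44, 7.2), ("M16", "TURB"): (82.38, 66.69),
    ("M6", "DO"): (6.91, 1.15), ("M8", "DO"): (4.31, 1.44),
    ("M13", "EC"): (262.25, 74.99), ("M15", "EC"): (73.50, 23.72),
    ("M13", "TDS"): (172.28, 61.65), ("M15", "TDS"): (51.44, 16.6),
    ("M16", "TSS"): (298.75, 343.81), ("M12", "TSS"): (287.75, 288.54),
    ("M6", "TSS"): (52.42, 30.99),
    ("M6", "CHL_A"): (1.95, 0.63), ("M5", "CHL_A"): (6.55, 2.85),
    ("M8", "PH"): (6.80, 0.24), ("M6", "PH"): (7.30, 0.30),
    ("M15", "TN"): (2.95, 0.88), ("M9", "TN"): (4.91, 0.87),
    ("M9", "NO3_N"): (3.46, 0.78), ("M13", "NO3_N"): (3.01, 1.31),
    ("M1", "NO3_N"): (1.91, 0.74),
    ("M3", "NO2_N"): (0.01, 0.01), ("M6", "NO2_N"): (0.11, 0.12),
    ("M6", "NH4_N"): (0.07, 0.04), ("M1", "NH4_N"): (0.41, 0.32),
    ("M6", "TP"): (0.16, 0.19), ("M14", "TP"): (0.40, 0.46),
    ("M16", "TP"): (0.40, 0.57),
    ("M13", "SRP"): (0.03, 0.02), ("M2", "SRP"): (0.11, 0.10),
    ("M8", "SRP"): (0.11, 0.08), ("M9", "SRP"): (0.11, 0.19),
}

# Wet-season multipliers on the cell mean (dry season is the 1.0 baseline).
# Runoff raises particulates and the wash-off nutrients; rainfall dilutes
# conductivity and the major ions.
_WET_MULT: dict[str, float] = {
    "TURB": 1.4, "TSS": 1.5, "NH4_N": 1.15, "SRP": 1.2, "TN": 1.1,
    "CHL_A": 1.1, "WT": 1.05,
    "EC": 0.85, "TDS": 0.85, "NA": 0.85, "K": 0.9, "CL": 0.9, "SO4": 0.9,
    "TH": 0.9, "NO3_N": 0.9, "NO2_N": 0.95, "DO": 0.95, "PH": 1.0,
}

_PH_RANGE = (5.0, 9.0)


@dataclass(frozen=True)
class SyntheticScenario:
    """Station×parameter mean/SD table plus seasonal multipliers and seed."""

    stations: tuple[str, ...]
    months: tuple[str, ...] = DEFAULT_MONTHS
    cell_params: Mapping[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    season_multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_family: str = "lognormal"
    seed: int = 0
    anchors: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.noise_family not in ("lognormal", "truncated-normal"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")
        for (s, p), (m, sd) in self.cell_params.items():
            if sd < 0:
                raise ValueError(f"({s},{p}): negative sd {sd}")
            if p == "PH":
                if not _PH_RANGE[0] <= m <= _PH_RANGE[1]:
                    raise ValueError(f"({s},{p}): pH mean {m} outside {_PH_RANGE}")
            elif m <= 0:
                raise ValueError(f"({s},{p}): non-positive mean {m}")

    def multiplier(self, parameter: str, season: str) -> float:
        return float(self.season_multipliers.get((parameter, season), 1.0))


def _interp(u: float, line) -> tuple[float, float]:
    (ua, ma, cva), (ub, mb, cvb), scale = line
    t = (u - ua) / (ub - ua)
    if scale == "log":
        mean = math.exp(math.log(ma) + t * (math.log(mb) - math.log(ma)))
    else:
        mean = ma + t * (mb - ma)
    cv = cva + min(max(t, 0.0), 1.0) * (cvb - cva)
    return mean, cv * mean


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The packaged 16-station × 19-parameter scenario described above."""
    params = [p.code for p in default_standards()]
    stations = tuple(PRESSURE)
    cells: dict[tuple[str, str], tuple[float, float]] = {}
    for s in stations:
        u = PRESSURE[s]
        for code in params:
            if code in _LINES:
                mean, sd = _interp(u, _LINES[code])
            elif code == "NH4_N":
                mean = _NH4_MEANS[s]
                sd = 0.65 * mean
            else:
                mean, sd = _FLAT[code]
            cells[(s, code)] = (mean, sd)
    for key, ms in ANCHORS.items():
        cells[key] = ms
    mults = {(code, "wet"): m for code, m in _WET_MULT.items()}
    return SyntheticScenario(stations=stations, cell_params=cells,
                             season_multipliers=mults, seed=seed,
                             anchors=tuple(ANCHORS))


def with_wet_cpi_multiplier(scenario: SyntheticScenario,
                            multiplier: float) -> SyntheticScenario:
    """Override the wet-season multiplier of every CPI parameter.

    Non-DO CPI parameters get ``multiplier`` on the wet-season mean; DO gets
    its reciprocal so that oxygen depletion, and hence the inverted
    pollution index, moves in the same (polluting) direction.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    mults = dict(scenario.season_multipliers)
    for p in default_standards():
        if p.in_cpi:
            mults[(p.code, "wet")] = (1.0 / multiplier) if p.do_like else multiplier
    return replace(scenario, season_multipliers=mults)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # Exact moment matching for the lognormal family.
    var = sd * sd
    mu = math.log(mean * mean / math.sqrt(mean * mean + var))
    sigma = math.sqrt(math.log(1.0 + var / (mean * mean)))
    return mu, sigma


def _draw(rng: np.random.Generator, parameter: str, means: np.ndarray,
          sd: float, family: str) -> np.ndarray:
    """One value per entry of ``means``, from a single standard-normal batch."""
    means = np.asarray(means, dtype=float)
    z = rng.standard_normal(means.shape)
    if parameter == "PH":
        return np.clip(means + sd * z, *_PH_RANGE)
    if sd == 0:
        return means.copy()
    if family == "lognormal":
        var = sd * sd
        mu = np.log(means * means / np.sqrt(means * means + var))
        sigma = np.sqrt(np.log(1.0 + var / (means * means)))
        return np.exp(mu + sigma * z)
    # truncated-normal fallback: clip at a small positive floor
    return np.maximum(means + sd * z, means * 1e-3)


def draw_cell(scenario: SyntheticScenario, station: str, parameter: str,
              n: int, rng: np.random.Generator) -> np.ndarray:
    """Replicate draws from one cell at its unmodified (dry-baseline) mean."""
    mean, sd = scenario.cell_params[(station, parameter)]
    return _draw(rng, parameter, np.full(n, mean), sd, scenario.noise_family)


def generate_frame(scenario: SyntheticScenario,
                   seed: int | None = None) -> pd.DataFrame:
    """Generate the long-format dataset ``station,period,parameter,value``."""
    from .seasonal import season_of  # local import to avoid a cycle

    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    months = list(scenario.months)
    seasons = [season_of(int(m.split("-")[1])) for m in months]
    params = sorted({p for (_, p) in scenario.cell_params})
    rows = []
    for station in scenario.stations:
        for code in params:
            if (station, code) not in scenario.cell_params:
                continue
            mean, sd = scenario.cell_params[(station, code)]
            mults = np.array([scenario.multiplier(code, s) for s in seasons])
            # Season scales the mean only; the cell SD is held fixed.
            values = _draw(rng, code, mean * mults, sd, scenario.noise_family)
            for m, v in zip(months, values):
                rows.append((station, m, code, float(v)))
    return pd.DataFrame(rows, columns=["station", "period", "parameter", "value"])


def generate(scenario: SyntheticScenario,
             seed: int | None = None) -> list[MonitoringRecord]:
    """Generate monitoring records; identical seeds give identical data."""
    frame = generate_frame(scenario, seed=seed)
    records = []
    for station in scenario.stations:          # preserve scenario order
        sub = frame[frame["station"] == station]
        for period in scenario.months:
            grp = sub[sub["period"] == period]
            records.append(MonitoringRecord(
                station=station, period=period,
                values=dict(zip(grp["parameter"], grp["value"])),
            ))
    return records
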