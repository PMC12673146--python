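"""Monitoring records and station metadata.

A monitoring record is one station-month sample: a station code, an ISO
``YYYY-MM`` period and a parameter→value map.  Station metadata (16 sampling
stations of the Maziba sub-catchment with their contributing areas and
coordinates) ships as a packaged CSV fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "MonitoringRecord",
    "StationMeta",
    "load_station_metadata",
    "station_metadata_frame",
    "records_to_frame",
    "frame_to_records",
]


def _parse_period(period: str) -> datetime:
    try:
        return datetime.strptime(period, "%Y-%m")
    except (TypeError, ValueError) as exc:
        raise ValueError(f"period {period!r} is not a valid YYYY-MM month") from exc


@dataclass(frozen=True)
class MonitoringRecord:
    """One station-month sample.

    Concentrations must be non-negative; pH (code ``PH``) is unitless and
    must lie in [0, 14].
    """

    station: str
    period: str
    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _parse_period(self.period)
        for code, v in self.values.items():
            if v is None or pd.isna(v):
                continue
            if code == "PH":
                if not 0.0 <= v <= 14.0:
                    raise ValueError(
                        f"{self.station} {self.period}: pH {v} outside [0, 14]"
                    )
            elif v < 0:
                raise ValueError(
                    f"{self.station} {self.period}: negative {code} value {v}"
                )

    @property
    def month(self) -> int:
        return _parse_period(self.period).month


@dataclass(frozen=True)
class StationMeta:
    """A sampling station and the upstream drainage area it integrates."""

    code: str
    name: str
    subcatchment_km2: float
    upstream_km2: float
    altitude_m: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not self.subcatchment_km2 > 0:
            raise ValueError(f"{self.code}: sub-catchment area must be positive")
        if self.upstream_km2 < self.subcatchment_km2:
            raise ValueError(
                f"{self.code}: upstream area {self.upstream_km2} smaller than "
                f"sub-catchment area {self.subcatchment_km2}"
            )


def station_metadata_frame() -> pd.DataFrame:
    """The packaged 16-station metadata table as a DataFrame."""
    with resources.files("aquarisk.data").joinpath("stations.csv").open("r") as fh:
        return pd.read_csv(fh)


def load_station_metadata() -> list[StationMeta]:
    return [StationMeta(**row) for row in station_metadata_frame().to_dict("records")]


def records_to_frame(records: list[MonitoringRecord]) -> pd.DataFrame:
    """Long-format DataFrame ``station,period,parameter,value``."""
    rows = [
        (r.station, r.period, code, v)
        for r in records
        for code, v in r.values.items()
    ]
    return pd.DataFrame(rows, columns=["station", "period", "parameter", "value"])


def frame_to_records(frame: pd.DataFrame) -> list[MonitoringRecord]:
    """Inverse of :func:`records_to_frame`; one record per station-month."""
    records = []
    for (station, period), grp in frame.groupby(["station", "period"], sort=True):
        records.append(
            MonitoringRecord(
                station=str(station),
                period=str(period),
                values=dict(zip(grp["parameter"], grp["value"])),
            )
        )
    return records
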