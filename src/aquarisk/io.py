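"""Readers, writers, dataset adapter and the end-to-end pipeline.

The canonical interchange format is a long CSV ``station,period,parameter,
value`` with ISO ``YYYY-MM`` periods; wide tables (one column per
parameter) are supported through a :class:`ColumnMapping`, which also
serves as the adapter for externally published datasets whose column
names differ from the canonical codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cpi import CpiScorer, classify_cpi
from .records import MonitoringRecord, frame_to_records, records_to_frame
from .risk import classify_risk
from .seasonal import (
    SeasonCalendar, risk_distribution, season_of, seasonal_compare,
)
from .standards import (
    ParameterDef, default_standards, load_standards, standards_checksum,
)
from .wawqi import WawqiScorer, classify_wawqi

logger = logging.getLogger("aquarisk")

__all__ = [
    "ColumnMapping",
    "RunConfig",
    "ReportBundle",
    "read_monitoring_table",
    "write_monitoring_table",
    "load_zenodo_mapping",
    "run_pipeline",
]


@dataclass(frozen=True)
class ColumnMapping:
    """Maps source columns of a monitoring table onto canonical codes.

    ``layout="long"`` expects station/date/parameter/value columns, with
    ``columns`` translating parameter names; ``layout="wide"`` expects one
    column per parameter, with ``columns`` translating column headers.
    """

    layout: str = "long"
    station: str = "station"
    date: str = "period"
    parameter: str = "parameter"
    value: str = "value"
    columns: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layout not in ("long", "wide"):
            raise ValueError(f"unknown layout {self.layout!r}")
        codes = list(self.columns.values())
        if len(set(codes)) != len(codes):
            raise ValueError("column mapping maps two source columns to one code")


def load_zenodo_mapping() -> ColumnMapping:
    """The packaged best-effort adapter template for the published Maziba
    monitoring deposit (finalise against the actual files after download)."""
    text = resources.files("aquarisk.data").joinpath("zenodo_mapping.yaml").read_text()
    payload = yaml.safe_load(text)
    return ColumnMapping(layout=payload["layout"], station=payload["station"],
                         date=payload["date"], columns=payload["columns"])


def _normalise_period(raw) -> str:
    ts = pd.to_datetime(raw)
    return f"{ts.year}-{ts.month:02d}"


def read_monitoring_table(path: str | Path,
                          mapping: ColumnMapping | None = None,
                          policy: str = "lenient") -> list[MonitoringRecord]:
    """Read a monitoring CSV into validated records.

    Rows that violate the record invariants (negative concentration, pH
    outside [0, 14], bad date) are skipped with a logged warning under the
    ``lenient`` policy and raise under ``strict``.
    """
    if policy not in ("lenient", "strict"):
        raise ValueError(f"unknown validation policy {policy!r}")
    mapping = mapping or ColumnMapping()
    # keep_default_na=False so the sodium code "NA" survives as a string;
    # empty cells still count as missing; round_trip parsing so written
    # values come back bit-identical.
    frame = pd.read_csv(path, keep_default_na=False, na_values=[""],
                        float_precision="round_trip")
    for col in (mapping.station, mapping.date):
        if col not in frame.columns:
            raise ValueError(f"required column {col!r} missing from {path}")

    if mapping.layout == "long":
        for col in (mapping.parameter, mapping.value):
            if col not in frame.columns:
                raise ValueError(f"required column {col!r} missing from {path}")
        long = frame.rename(columns={
            mapping.station: "station", mapping.date: "period",
            mapping.parameter: "parameter", mapping.value: "value",
        })[["station", "period", "parameter", "value"]].copy()
        if mapping.columns:
            long["parameter"] = long["parameter"].map(
                lambda p: mapping.columns.get(p, p))
    else:
        param_cols = {c: mapping.columns.get(c, c) for c in frame.columns
                      if c not in (mapping.station, mapping.date)}
        long = frame.melt(id_vars=[mapping.station, mapping.date],
                          value_vars=list(param_cols),
                          var_name="parameter", value_name="value")
        long["parameter"] = long["parameter"].map(param_cols)
        long = long.rename(columns={mapping.station: "station",
                                    mapping.date: "period"})

    long["value"] = pd.to_numeric(long["value"], errors="coerce")
    long = long.dropna(subset=["value"])

    records: list[MonitoringRecord] = []
    for (station, period), grp in long.groupby(["station", "period"], sort=True):
        try:
            iso = _normalise_period(period)
            records.append(MonitoringRecord(
                station=str(station), period=iso,
                values=dict(zip(grp["parameter"], grp["value"]))))
        except (ValueError, TypeError) as exc:
            if policy == "strict":
                raise ValueError(
                    f"invalid sample {station} {period}: {exc}") from exc
            logger.warning("skipping sample %s %s (rows %s): %s",
                           station, period, list(grp.index[:3]), exc)
    return records


def write_monitoring_table(records: Sequence[MonitoringRecord],
                           path: str | Path) -> None:
    """Write records as the canonical long CSV (floats at full %.17g
    precision so values round-trip exactly)."""
    records_to_frame(list(records)).to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run, echoed into its log."""

    standards_path: str | None = None
    pi_do: str = "inverted"
    missing: str = "renormalise"
    aggregation: str = "mean-of-indices"
    seed: int = 0
    calendar: SeasonCalendar | None = None

    def resolve_standards(self) -> list[ParameterDef]:
        if self.standards_path is None:
            return default_standards()
        return load_standards(self.standards_path)


@dataclass
class ReportBundle:
    """All pipeline outputs plus the run log."""

    samples: pd.DataFrame          # station,period,season,wawqi,wawqi_band,cpi,cpi_band,pi_mode
    station_summary: pd.DataFrame  # station,parameter,n,mean,sd
    station_risk: pd.DataFrame     # station,mean_wawqi,mean_cpi,risk_level
    seasonal: pd.DataFrame         # index,dry_n,wet_n,dry_mean,wet_mean,statistic,p_value
    risk_distribution: pd.DataFrame  # risk_level,count,fraction,percentage
    log: str

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = {"index": False, "float_format": "%.17g"}
        self.samples.to_csv(out / "sample_indices.csv", **kw)
        self.station_summary.to_csv(out / "station_summary.csv", **kw)
        self.station_risk.to_csv(out / "station_risk.csv", **kw)
        self.seasonal.to_csv(out / "seasonal_comparison.csv", **kw)
        self.risk_distribution.to_csv(out / "risk_distribution.csv", **kw)
        (out / "run_log.txt").write_text(self.log, encoding="utf-8")


def run_pipeline(records: Sequence[MonitoringRecord],
                 config: RunConfig | None = None) -> ReportBundle:
    """Score every record, aggregate per station and season, classify risk.

    Deterministic: identical records and config give identical outputs.
    """
    config = config or RunConfig()
    if not records:
        raise ValueError("pipeline stage 'scoring': empty input table")
    standards = config.resolve_standards()
    calendar = config.calendar

    long = records_to_frame(list(records))
    wide = long.pivot_table(index=["station", "period"], columns="parameter",
                            values="value", aggfunc="mean")

    wscorer = WawqiScorer(standards=standards, missing=config.missing).fit()
    cscorer = CpiScorer(standards=standards, do_mode=config.pi_do).fit()
    wawqi = wscorer.score_samples(wide)
    cpi = cscorer.score_samples(wide)

    samples = wide.reset_index()[["station", "period"]].copy()
    samples["season"] = [season_of(int(p.split("-")[1]), calendar)
                         for p in samples["period"]]
    samples["wawqi"] = wawqi
    samples["wawqi_band"] = [classify_wawqi(s) for s in wawqi]
    samples["cpi"] = cpi
    samples["cpi_band"] = [classify_cpi(c) for c in cpi]
    samples["pi_mode"] = config.pi_do

    summary = (
        long.groupby(["station", "parameter"])["value"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )

    rows = []
    for station, grp in samples.groupby("station", sort=True):
        if config.aggregation == "mean-of-indices":
            mw, mc = float(grp["wawqi"].mean()), float(grp["cpi"].mean())
        elif config.aggregation == "index-of-means":
            mean_sample = wide.loc[station].mean(axis=0, skipna=True).to_frame().T
            mw = float(wscorer.score_samples(mean_sample)[0])
            mc = float(cscorer.score_samples(mean_sample)[0])
        else:
            raise ValueError(f"unknown aggregation mode {config.aggregation!r}")
        rows.append((station, mw, mc, classify_risk(mw, mc).level))
    station_risk = pd.DataFrame(
        rows, columns=["station", "mean_wawqi", "mean_cpi", "risk_level"])

    seas_rows = []
    for index_col in ("wawqi", "cpi"):
        dry = samples.loc[samples["season"] == "dry", index_col].to_numpy()
        wet = samples.loc[samples["season"] == "wet", index_col].to_numpy()
        if dry.size and wet.size:
            test = seasonal_compare(dry, wet)
            seas_rows.append((index_col, dry.size, wet.size, dry.mean(),
                              wet.mean(), test["statistic"], test["p_value"]))
    seasonal = pd.DataFrame(seas_rows, columns=[
        "index", "dry_n", "wet_n", "dry_mean", "wet_mean", "statistic", "p_value"])

    dist = risk_distribution(list(station_risk["risk_level"]))
    dist_frame = pd.DataFrame({
        "risk_level": list(dist.counts),
        "count": list(dist.counts.values()),
        "fraction": list(dist.fractions.values()),
        "percentage": list(dist.percentages.values()),
    })

    cfg = {k: v for k, v in asdict(config).items() if k != "calendar"}
    log = "\n".join([
        "aquarisk pipeline run",
        f"config: {cfg}",
        f"n_records: {len(records)}",
        f"n_stations: {station_risk.shape[0]}",
        f"standards_checksum: {standards_checksum(standards)}",
        "",
    ])
    return ReportBundle(samples=samples, station_summary=summary,
                        station_risk=station_risk, seasonal=seasonal,
                        risk_distribution=dist_frame, log=log)
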