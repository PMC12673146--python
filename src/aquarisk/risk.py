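"""Combined drinking-water / ecosystem-health risk matrix.

A station's (WAWQI, CPI) pair is mapped through a 3×3 decision table to
one of five stakeholder-oriented risk levels:

=====================  ==================  ========================  ============
WAWQI \\ CPI            ≤ 0.4               (0.4, 2.0]                > 2.0
=====================  ==================  ========================  ============
≤ 50                   Low Risk            Moderate Risk (Ecosystem)  Severe Risk
(50, 100]              Moderate (Drinking) High Risk                  Severe Risk
> 100                  Severe Risk         Severe Risk                Severe Risk
=====================  ==================  ========================  ============

Severe Risk applies whenever either index alone crosses its worst
threshold (WAWQI > 100 or CPI > 2.0).  Boundaries close from above:
a score exactly at 50, 100, 0.4 or 2.0 stays in the milder cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cpi import CpiScorer
from .records import MonitoringRecord, records_to_frame
from .standards import ParameterDef
from .wawqi import WawqiScorer

__all__ = [
    "RiskResult",
    "RISK_LEVELS",
    "RISK_SEVERITY",
    "classify_risk",
    "station_risk",
    "RiskClassifier",
]

RISK_LEVELS = (
    "Low Risk",
    "Moderate Risk (Ecosystem)",
    "Moderate Risk (Drinking)",
    "High Risk",
    "Severe Risk",
)

# Partial severity order; the two Moderate variants rank equal.
RISK_SEVERITY = {
    "Low Risk": 0,
    "Moderate Risk (Ecosystem)": 1,
    "Moderate Risk (Drinking)": 1,
    "High Risk": 2,
    "Severe Risk": 3,
}


@dataclass(frozen=True)
class RiskResult:
    wawqi: float
    cpi: float
    wawqi_band_group: str  # "<=50", "(50,100]", ">100"
    cpi_band_group: str    # "<=0.4", "(0.4,2.0]", ">2.0"
    level: str


def _wawqi_group(w: float) -> str:
    return "<=50" if w <= 50.0 else "(50,100]" if w <= 100.0 else ">100"


def _cpi_group(c: float) -> str:
    return "<=0.4" if c <= 0.4 else "(0.4,2.0]" if c <= 2.0 else ">2.0"


_MATRIX = {
    ("<=50", "<=0.4"): "Low Risk",
    ("<=50", "(0.4,2.0]"): "Moderate Risk (Ecosystem)",
    ("<=50", ">2.0"): "Severe Risk",
    ("(50,100]", "<=0.4"): "Moderate Risk (Drinking)",
    ("(50,100]", "(0.4,2.0]"): "High Risk",
    ("(50,100]", ">2.0"): "Severe Risk",
    (">100", "<=0.4"): "Severe Risk",
    (">100", "(0.4,2.0]"): "Severe Risk",
    (">100", ">2.0"): "Severe Risk",
}


def classify_risk(wawqi: float, cpi: float) -> RiskResult:
    """Classify a (WAWQI, CPI) pair through the 3×3 risk matrix."""
    if wawqi < 0 or cpi < 0 or not (np.isfinite(wawqi) and np.isfinite(cpi)):
        raise ValueError(f"indices must be finite and non-negative, got ({wawqi}, {cpi})")
    wg, cg = _wawqi_group(wawqi), _cpi_group(cpi)
    return RiskResult(wawqi=wawqi, cpi=cpi, wawqi_band_group=wg,
                      cpi_band_group=cg, level=_MATRIX[(wg, cg)])


class RiskClassifier(BaseEstimator):
    """Predict risk levels from a two-column (wawqi, cpi) input.

    A stateless sklearn-style classifier over the published decision table;
    ``fit`` only records the class labels.
    """

    def __init__(self):
        pass

    def fit(self, X=None, y=None) -> "RiskClassifier":
        self.classes_ = np.array(RISK_LEVELS)
        return self

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[["wawqi", "cpi"]] if {"wawqi", "cpi"} <= set(X.columns) else X
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected a two-column (wawqi, cpi) input")
        return np.array([classify_risk(w, c).level for w, c in X])


def station_risk(records: Sequence[MonitoringRecord],
                 standards: Sequence[ParameterDef] | None = None,
                 do_mode: str = "inverted",
                 missing: str = "renormalise",
                 aggregation: str = "mean-of-indices") -> RiskResult:
    """Classify one station from its monthly records.

    ``mean-of-indices`` (default) computes a WAWQI and CPI per monthly
    record and classifies the pair of means; ``index-of-means`` first
    averages each parameter over the months and scores the mean sample.
    """
    if not records:
        raise ValueError("station_risk needs at least one record")
    if aggregation not in ("mean-of-indices", "index-of-means"):
        raise ValueError(f"unknown aggregation mode {aggregation!r}")
    long = records_to_frame(list(records))
    wide = long.pivot_table(index=["station", "period"], columns="parameter",
                            values="value", aggfunc="mean")
    wscorer = WawqiScorer(standards=standards, missing=missing).fit()
    cscorer = CpiScorer(standards=standards, do_mode=do_mode).fit()
    if aggregation == "mean-of-indices":
        mean_w = float(np.mean(wscorer.score_samples(wide)))
        mean_c = float(np.mean(cscorer.score_samples(wide)))
    else:
        mean_sample = wide.mean(axis=0, skipna=True).to_frame().T
        mean_w = float(wscorer.score_samples(mean_sample)[0])
        mean_c = float(cscorer.score_samples(mean_sample)[0])
    return classify_risk(mean_w, mean_c)
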