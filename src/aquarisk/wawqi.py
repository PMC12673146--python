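"""Weighted Arithmetic Water Quality Index (WAWQI) for drinking-water suitability.

Each parameter gets a quality rating

    Q_n = 100 * |V_n - V_i| / |S_n - V_i|

where V_n is the measured value, V_i the ideal value (0 for most
parameters, 14.6 mg/L for dissolved oxygen, 7 for pH) and S_n the
permissible standard.  Q_n is 0 at the ideal and 100 at the standard.
The index is the weighted mean

    WAWQI = Σ Q_n W_n / Σ W_n

with unit weights W_n = K / S_n, and is binned into five drinking-water
classes from Excellent (0–25) to Unfit for human consumption (> 100).

The scorer is an sklearn-compatible transformer: ``fit`` resolves the
standards registry into weights, ``transform`` maps a DataFrame with
parameter columns to a column of index scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .standards import ParameterDef, default_standards, unit_weights

__all__ = [
    "QualityRating",
    "WawqiResult",
    "WAWQI_BANDS",
    "quality_rating",
    "classify_wawqi",
    "compute_wawqi",
    "WawqiScorer",
]

WAWQI_BANDS = ("Excellent", "Good", "Poor", "Very poor", "Unfit")
# Upper edges of the printed integer ranges, applied as half-open intervals
# closing on the upper bound: [0,25], (25,50], (50,75], (75,100], (100,inf).
_BAND_EDGES = (25.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class QualityRating:
    """Per-parameter rating: Q_n = 0 at the ideal value, 100 at the standard."""

    parameter: str
    Vn: float
    Qn: float
    Wn: float


@dataclass(frozen=True)
class WawqiResult:
    score: float
    ratings: tuple[QualityRating, ...]
    band: str


def classify_wawqi(score: float) -> str:
    """Map a WAWQI score to its drinking-water class."""
    if score < 0 or not np.isfinite(score):
        raise ValueError(f"WAWQI score must be a finite non-negative real, got {score}")
    for band, edge in zip(WAWQI_BANDS, _BAND_EDGES):
        # snap scores within float rounding of an edge onto the edge, so an
        # all-at-standard sample (exactly 100 in exact arithmetic) bands as
        # the edge value does
        if score <= edge or abs(score - edge) <= 1e-12 * edge:
            return band
    return WAWQI_BANDS[-1]


def quality_rating(value: float, pdef: ParameterDef) -> float:
    """Quality rating Q_n of one measured value against its standard."""
    if not pdef.in_wawqi:
        raise ValueError(f"{pdef.code} is not a WAWQI parameter")
    return 100.0 * abs(value - pdef.wawqi_ideal) / abs(pdef.wawqi_standard - pdef.wawqi_ideal)


class WawqiScorer(TransformerMixin, BaseEstimator):
    """Transform parameter columns into WAWQI scores.

    Parameters
    ----------
    standards : sequence of ParameterDef or None
        Registry to score against; the packaged defaults when None.
    missing : {"renormalise", "strict"}
        Missing-data policy.  ``renormalise`` drops a missing parameter from
        both Σ Q_n W_n and Σ W_n (the weighted-mean-preserving choice);
        ``strict`` raises instead.

    Attributes
    ----------
    k_ : proportionality constant of the fitted registry.
    weights_ : dict of unit weights W_n per parameter code.
    params_ : the fitted WAWQI parameter definitions, keyed by code.
    """

    def __init__(self, standards: Sequence[ParameterDef] | None = None,
                 missing: str = "renormalise"):
        self.standards = standards
        self.missing = missing

    def fit(self, X=None, y=None) -> "WawqiScorer":
        if self.missing not in ("renormalise", "strict"):
            raise ValueError(f"unknown missing-data policy {self.missing!r}")
        standards = self.standards if self.standards is not None else default_standards()
        table = unit_weights(standards)
        self.k_ = table.K
        self.weights_ = dict(table.weights)
        self.params_ = {p.code: p for p in standards if p.in_wawqi}
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise AttributeError("WawqiScorer is not fitted; call fit() first")

    def rating_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-parameter quality ratings Q_n, NaN where a value is missing."""
        self._check_fitted()
        out = {}
        for code, p in self.params_.items():
            if code in X.columns:
                v = pd.to_numeric(X[code], errors="coerce").to_numpy(dtype=float)
                out[code] = 100.0 * np.abs(v - p.wawqi_ideal) / abs(
                    p.wawqi_standard - p.wawqi_ideal
                )
            else:
                out[code] = np.full(len(X), np.nan)
        return pd.DataFrame(out, index=X.index)

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        """WAWQI score per row of a parameter-column DataFrame."""
        q = self.rating_frame(X)
        present = q.notna().to_numpy()
        if self.missing == "strict" and not present.all():
            missing = sorted(q.columns[q.isna().any()])
            raise ValueError(f"missing WAWQI parameters under strict policy: {missing}")
        if not present.any(axis=1).all():
            bad = list(X.index[~present.any(axis=1)])
            raise ValueError(f"rows with no WAWQI parameters at all: {bad[:5]}")
        w = np.array([self.weights_[c] for c in q.columns])
        qw = np.where(present, q.to_numpy() * w, 0.0)
        wsum = (present * w).sum(axis=1)
        return qw.sum(axis=1) / wsum

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_samples(X).reshape(-1, 1)

    def classify(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([classify_wawqi(s) for s in self.score_samples(X)])


def compute_wawqi(values: Mapping[str, float],
                  standards: Sequence[ParameterDef] | None = None,
                  missing: str = "renormalise") -> WawqiResult:
    """Score one sample (parameter→value map) and classify it."""
    scorer = WawqiScorer(standards=standards, missing=missing).fit()
    X = pd.DataFrame([values])
    score = float(scorer.score_samples(X)[0])
    q = scorer.rating_frame(X).iloc[0]
    ratings = tuple(
        QualityRating(parameter=c, Vn=float(values[c]), Qn=float(q[c]),
                      Wn=scorer.weights_[c])
        for c in q.index
        if not np.isnan(q[c])
    )
    return WawqiResult(score=score, ratings=ratings, band=classify_wawqi(score))
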