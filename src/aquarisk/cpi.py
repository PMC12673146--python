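"""Comprehensive Pollution Index (CPI) for aquatic ecosystem health.

Each of the nine CPI parameters contributes a single-factor pollution
index PI_i = C_i / S_i (measured value over standard); the CPI is their
arithmetic mean.  A CPI of 1.0 means the water sits, on average, exactly
at the standards.  Five classes run from No Apparent Impact (≤ 0.2) to
Severely Impacted (> 2.0).

Dissolved oxygen is the one parameter for which more is better.  Taken
literally, PI = DO/S would reward oxygen depletion, so the default
(``do_mode="inverted"``) uses PI = S/DO; the literal ratio remains
available and the mode is stamped into every output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .standards import ParameterDef, default_standards

__all__ = [
    "CpiResult",
    "CPI_BANDS",
    "pollution_index",
    "classify_cpi",
    "compute_cpi",
    "CpiScorer",
]

CPI_BANDS = (
    "No Apparent Impact",
    "Minimal Impact",
    "Slightly Impacted",
    "Moderately Impacted",
    "Severely Impacted",
)
# [0,0.2], (0.2,0.4], (0.4,1.0], (1.0,2.0], (2.0,inf)
_BAND_EDGES = (0.2, 0.4, 1.0, 2.0)


@dataclass(frozen=True)
class CpiResult:
    cpi: float
    pis: Mapping[str, float]
    band: str
    n: int
    do_mode: str


def classify_cpi(cpi: float) -> str:
    """Map a CPI value to its ecosystem-health class."""
    if cpi < 0 or not np.isfinite(cpi):
        raise ValueError(f"CPI must be a finite non-negative real, got {cpi}")
    for band, edge in zip(CPI_BANDS, _BAND_EDGES):
        # snap float-rounding neighbours of an edge onto the edge (an
        # all-at-standard sample is exactly 1.0 in exact arithmetic)
        if cpi <= edge or abs(cpi - edge) <= 1e-12 * edge:
            return band
    return CPI_BANDS[-1]


def pollution_index(value: float, pdef: ParameterDef, do_mode: str = "inverted") -> float:
    """Single-factor pollution index of one measured value."""
    if not pdef.in_cpi:
        raise ValueError(f"{pdef.code} is not a CPI parameter")
    if do_mode not in ("inverted", "literal"):
        raise ValueError(f"unknown DO mode {do_mode!r}")
    if pdef.do_like and do_mode == "inverted":
        if value <= 0:
            raise ValueError(
                f"{pdef.code}={value}: inverted pollution index undefined at zero"
            )
        return pdef.cpi_standard / value
    return value / pdef.cpi_standard


class CpiScorer(TransformerMixin, BaseEstimator):
    """Transform parameter columns into CPI values.

    ``n`` in the mean counts the parameters actually present in each row
    (renormalisation on missing data, mirroring the WAWQI policy).

    Attributes
    ----------
    params_ : fitted CPI parameter definitions keyed by code.
    standards_ : dict of CPI standards S_i per code.
    """

    def __init__(self, standards: Sequence[ParameterDef] | None = None,
                 do_mode: str = "inverted"):
        self.standards = standards
        self.do_mode = do_mode

    def fit(self, X=None, y=None) -> "CpiScorer":
        if self.do_mode not in ("inverted", "literal"):
            raise ValueError(f"unknown DO mode {self.do_mode!r}")
        standards = self.standards if self.standards is not None else default_standards()
        self.params_ = {p.code: p for p in standards if p.in_cpi}
        if not self.params_:
            raise ValueError("standards set has no CPI parameters")
        self.standards_ = {c: p.cpi_standard for c, p in self.params_.items()}
        return self

    def pi_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-parameter pollution indices, NaN where a value is missing."""
        if not hasattr(self, "params_"):
            raise AttributeError("CpiScorer is not fitted; call fit() first")
        out = {}
        for code, p in self.params_.items():
            if code in X.columns:
                v = pd.to_numeric(X[code], errors="coerce").to_numpy(dtype=float)
                if p.do_like and self.do_mode == "inverted":
                    if np.any(v[~np.isnan(v)] <= 0):
                        raise ValueError(
                            f"{code}: inverted pollution index undefined at <= 0"
                        )
                    out[code] = p.cpi_standard / v
                else:
                    out[code] = v / p.cpi_standard
            else:
                out[code] = np.full(len(X), np.nan)
        return pd.DataFrame(out, index=X.index)

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        pis = self.pi_frame(X)
        n = pis.notna().sum(axis=1).to_numpy()
        if (n == 0).any():
            bad = list(X.index[n == 0])
            raise ValueError(f"rows with no CPI parameters at all: {bad[:5]}")
        return pis.mean(axis=1, skipna=True).to_numpy()

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_samples(X).reshape(-1, 1)

    def classify(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([classify_cpi(c) for c in self.score_samples(X)])


def compute_cpi(values: Mapping[str, float],
                standards: Sequence[ParameterDef] | None = None,
                do_mode: str = "inverted") -> CpiResult:
    """Score one sample (parameter→value map) and classify it."""
    scorer = CpiScorer(standards=standards, do_mode=do_mode).fit()
    X = pd.DataFrame([values])
    pis_row = scorer.pi_frame(X).iloc[0]
    pis = {c: float(v) for c, v in pis_row.items() if not np.isnan(v)}
    if not pis:
        raise ValueError("no CPI parameters present in the sample")
    cpi = float(np.mean(list(pis.values())))
    return CpiResult(cpi=cpi, pis=pis, band=classify_cpi(cpi), n=len(pis),
                     do_mode=do_mode)
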