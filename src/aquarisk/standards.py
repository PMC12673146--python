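"""Parameter standards registry and unit-weight arithmetic.

The drinking-water index (WAWQI) weights each parameter inversely to its
regulatory standard: W_n = K / S_n with K = 1 / Σ(1/S_n), so that the
weights sum to one.  The registry below carries, for each monitored
parameter, the WAWQI standard S_n and ideal value (zero for most,
14.6 mg/L for dissolved oxygen, 7 for pH), plus the separate standard used
by the ecosystem-health pollution index (CPI) where the parameter belongs
to that nine-member set.

Standards are configuration, not constants: a user-supplied YAML file can
replace the packaged defaults (national potable-water standards).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ParameterDef",
    "WeightTable",
    "StandardsError",
    "default_standards",
    "registry_by_code",
    "proportionality_constant",
    "unit_weights",
    "load_standards",
    "save_standards",
    "standards_checksum",
]


class StandardsError(ValueError):
    """Raised for an empty, non-positive or otherwise unusable standards set."""


@dataclass(frozen=True)
class ParameterDef:
    """One monitored physicochemical parameter and its index membership.

    Attributes
    ----------
    code : canonical ASCII identifier (e.g. ``"DO"``, ``"NH4_N"``).
    units : measurement units (mg/L, NTU, µS/cm, °C; unitless for pH).
    wawqi_standard : permissible value S_n used by the drinking-water index,
        required when ``in_wawqi``.
    wawqi_ideal : value at which the parameter contributes a zero quality
        rating (0 except DO = 14.6 mg/L and pH = 7).
    cpi_standard : standard S_i of the single-factor pollution index,
        required when ``in_cpi``.
    do_like : higher value means better quality (dissolved oxygen), which
        triggers the inverted pollution-index convention.
    """

    code: str
    name: str = ""
    units: str = ""
    wawqi_standard: float | None = None
    wawqi_ideal: float = 0.0
    cpi_standard: float | None = None
    in_wawqi: bool = False
    in_cpi: bool = False
    do_like: bool = False

    def __post_init__(self) -> None:
        if self.in_wawqi:
            if self.wawqi_standard is None or self.wawqi_standard <= 0:
                raise StandardsError(
                    f"{self.code}: WAWQI standard must be positive, got "
                    f"{self.wawqi_standard!r}"
                )
            if self.wawqi_standard == self.wawqi_ideal:
                raise StandardsError(
                    f"{self.code}: WAWQI standard equals the ideal value; the "
                    "quality rating would be undefined"
                )
            if self.wawqi_ideal < 0:
                raise StandardsError(f"{self.code}: ideal value must be >= 0")
        if self.in_cpi and (self.cpi_standard is None or self.cpi_standard <= 0):
            raise StandardsError(
                f"{self.code}: CPI standard must be positive, got "
                f"{self.cpi_standard!r}"
            )


@dataclass(frozen=True)
class WeightTable:
    """Unit weights W_n = K / S_n for the WAWQI parameter set."""

    K: float
    weights: Mapping[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.weights.values()))


# (code, name, units, S_n, ideal, CPI S_i, in_wawqi, in_cpi, do_like)
_DEFAULTS = [
    ("DO", "Dissolved oxygen", "mg/L", 6.0, 14.6, 8.0, True, True, True),
    ("PH", "pH", "", 8.5, 7.0, 8.5, True, True, False),
    ("TURB", "Turbidity", "NTU", 25.0, 0.0, 25.0, True, True, False),
    ("EC", "Electrical conductivity", "uS/cm", 2500.0, 0.0, 2500.0, True, True, False),
    ("NH4_N", "Ammonium nitrogen", "mg/L", 0.2, 0.0, 0.2, True, True, False),
    ("NO2_N", "Nitrite nitrogen", "mg/L", 3.0, 0.0, None, True, False, False),
    ("NO3_N", "Nitrate nitrogen", "mg/L", 13.29, 0.0, 13.29, True, True, False),
    ("SRP", "Soluble reactive phosphorus", "mg/L", 2.2, 0.0, 2.2, True, True, False),
    ("CL", "Chloride", "mg/L", 250.0, 0.0, 120.0, True, True, False),
    ("NA", "Sodium", "mg/L", 200.0, 0.0, None, True, False, False),
    ("SO4", "Sulphate", "mg/L", 400.0, 0.0, None, True, False, False),
    ("TH", "Total hardness", "mg/L", 200.0, 0.0, None, True, False, False),
    ("WT", "Water temperature", "degC", 25.0, 0.0, 27.0, True, True, False),
    # Monitored and summarised but members of neither index.
    ("TDS", "Total dissolved solids", "mg/L", None, 0.0, None, False, False, False),
    ("TSS", "Total suspended solids", "mg/L", None, 0.0, None, False, False, False),
    ("TP", "Total phosphorus", "mg/L", None, 0.0, None, False, False, False),
    ("TN", "Total nitrogen", "mg/L", None, 0.0, None, False, False, False),
    ("K", "Potassium", "mg/L", None, 0.0, None, False, False, False),
    ("CHL_A", "Chlorophyll a", "ug/L", None, 0.0, None, False, False, False),
]


def default_standards() -> list[ParameterDef]:
    """The packaged default registry: 19 monitored parameters, of which 13
    enter the WAWQI and 9 enter the CPI (CPI standards differ for DO, Cl⁻
    and temperature)."""
    return [
        ParameterDef(
            code=c, name=n, units=u, wawqi_standard=s, wawqi_ideal=iv,
            cpi_standard=cs, in_wawqi=w, in_cpi=p, do_like=d,
        )
        for c, n, u, s, iv, cs, w, p, d in _DEFAULTS
    ]


def registry_by_code(
    standards: Sequence[ParameterDef] | None = None,
) -> dict[str, ParameterDef]:
    return {p.code: p for p in (standards if standards is not None else default_standards())}


def _wawqi_members(standards: Iterable[ParameterDef]) -> list[ParameterDef]:
    members = [p for p in standards if p.in_wawqi]
    if not members:
        raise StandardsError("no WAWQI parameters in the standards set")
    for p in members:
        if p.wawqi_standard is None or p.wawqi_standard <= 0:
            raise StandardsError(f"{p.code}: non-positive WAWQI standard")
    return members


def proportionality_constant(standards: Sequence[ParameterDef]) -> float:
    """K = 1 / Σ(1/S_n) over the WAWQI members, normalising Σ W_n to 1."""
    members = _wawqi_members(standards)
    return 1.0 / sum(1.0 / p.wawqi_standard for p in members)


def unit_weights(standards: Sequence[ParameterDef]) -> WeightTable:
    """Unit weights W_n = K / S_n; inversely proportional to the standards."""
    members = _wawqi_members(standards)
    K = proportionality_constant(members)
    return WeightTable(K=K, weights={p.code: K / p.wawqi_standard for p in members})


# -- standards file format ---------------------------------------------------

_FIELDS = (
    "code", "name", "units", "wawqi_standard", "wawqi_ideal",
    "cpi_standard", "in_wawqi", "in_cpi", "do_like",
)


def save_standards(standards: Sequence[ParameterDef], path: str | Path) -> None:
    """Write a standards set to the flat YAML configuration format."""
    payload = {"parameters": [asdict(p) for p in standards]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def load_standards(path: str | Path | None = None) -> list[ParameterDef]:
    """Read a standards YAML file; with no path, read the packaged default."""
    if path is None:
        text = resources.files("aquarisk.data").joinpath("standards.yaml").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict) or "parameters" not in payload:
        raise StandardsError("standards file must contain a 'parameters' list")
    out = []
    for rec in payload["parameters"]:
        unknown = set(rec) - set(_FIELDS)
        if unknown:
            raise StandardsError(f"unknown standards fields: {sorted(unknown)}")
        out.append(ParameterDef(**rec))
    return out


def standards_checksum(standards: Sequence[ParameterDef]) -> str:
    """Stable SHA-256 of the standards table; stamped into run logs because
    index values are meaningless without the standards that produced them."""
    canon = yaml.safe_dump([asdict(p) for p in standards], sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()
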