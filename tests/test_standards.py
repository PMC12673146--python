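import math

import pytest
from hypothesis import given, settings, strategies as st

from aquarisk import (
    ParameterDef,
    StandardsError,
    default_standards,
    load_standards,
    load_station_metadata,
    proportionality_constant,
    save_standards,
    unit_weights,
)


class TestDefaultRegistry:
    def test_membership_counts(self, standards):
        assert len([p for p in standards if p.in_wawqi]) == 13
        assert len([p for p in standards if p.in_cpi]) == 9

    @pytest.mark.parametrize("code,sn", [
        ("DO", 6.0), ("PH", 8.5), ("TURB", 25.0), ("EC", 2500.0),
        ("NH4_N", 0.2), ("NO2_N", 3.0), ("NO3_N", 13.29), ("SRP", 2.2),
        ("CL", 250.0), ("NA", 200.0), ("SO4", 400.0), ("TH", 200.0),
        ("WT", 25.0),
    ])
    def test_wawqi_standards(self, by_code, code, sn):
        assert by_code[code].wawqi_standard == sn
        assert by_code[code].in_wawqi

    def test_ideals(self, by_code):
        assert by_code["DO"].wawqi_ideal == 14.6
        assert by_code["PH"].wawqi_ideal == 7.0
        others = [p for p in default_standards()
                  if p.in_wawqi and p.code not in ("DO", "PH")]
        assert all(p.wawqi_ideal == 0.0 for p in others)

    def test_cpi_overrides(self, by_code):
        # CPI standards equal the WAWQI ones except DO, chloride, temperature
        assert by_code["DO"].cpi_standard == 8.0
        assert by_code["CL"].cpi_standard == 120.0
        assert by_code["WT"].cpi_standard == 27.0
        for code in ("PH", "TURB", "EC", "NH4_N", "NO3_N", "SRP"):
            assert by_code[code].cpi_standard == by_code[code].wawqi_standard

    def test_do_is_the_only_inverted_parameter(self, standards):
        assert [p.code for p in standards if p.do_like] == ["DO"]

    def test_hardness_not_in_cpi(self, by_code):
        assert by_code["TH"].in_wawqi and not by_code["TH"].in_cpi

    def test_non_index_parameters_flagged(self, by_code):
        for code in ("TDS", "TSS", "TP", "TN", "K", "CHL_A"):
            assert not by_code[code].in_wawqi and not by_code[code].in_cpi


class TestWeights:
    def test_k_single_parameter(self):
        p = ParameterDef(code="X", wawqi_standard=5.0, in_wawqi=True)
        assert proportionality_constant([p]) == 5.0

    def test_k_symmetric_pair(self):
        ps = [ParameterDef(code=c, wawqi_standard=2.0, in_wawqi=True)
              for c in "AB"]
        assert proportionality_constant(ps) == pytest.approx(1.0)

    def test_k_default_registry(self, standards):
        # reciprocal sum 1/6 + 1/8.5 + ... + 1/25 ≈ 6.2443, inverted
        recip = sum(1.0 / p.wawqi_standard for p in standards if p.in_wawqi)
        assert recip == pytest.approx(6.244338, abs=1e-5)
        assert proportionality_constant(standards) == pytest.approx(0.1601451, abs=1e-6)

    def test_ammonium_dominates(self, standards):
        wt = unit_weights(standards)
        assert wt.weights["NH4_N"] == pytest.approx(0.8007255, abs=1e-6)
        assert max(wt.weights, key=wt.weights.get) == "NH4_N"

    def test_weights_sum_to_one(self, standards):
        assert unit_weights(standards).total() == pytest.approx(1.0, abs=1e-9)

    def test_weights_inverse_to_standards(self, standards):
        wt = unit_weights(standards)
        members = [p for p in standards if p.in_wawqi]
        for a in members:
            for b in members:
                if a.wawqi_standard < b.wawqi_standard:
                    assert wt.weights[a.code] > wt.weights[b.code]

    def test_empty_or_invalid_standards_rejected(self):
        with pytest.raises(StandardsError):
            proportionality_constant([])
        with pytest.raises(StandardsError):
            ParameterDef(code="X", wawqi_standard=-1.0, in_wawqi=True)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e4), min_size=1,
                    max_size=20))
    def test_weight_sum_property(self, sns):
        ps = [ParameterDef(code=f"P{i}", wawqi_standard=s, in_wawqi=True)
              for i, s in enumerate(sns)]
        assert unit_weights(ps).total() == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(min_value=1e-2, max_value=1e3), min_size=2,
                    max_size=10),
           st.floats(min_value=1e-2, max_value=1e3))
    def test_weights_scale_covariant(self, sns, c):
        base = [ParameterDef(code=f"P{i}", wawqi_standard=s, in_wawqi=True)
                for i, s in enumerate(sns)]
        scaled = [ParameterDef(code=p.code, wawqi_standard=c * p.wawqi_standard,
                               in_wawqi=True) for p in base]
        w0, w1 = unit_weights(base).weights, unit_weights(scaled).weights
        for code in w0:
            assert w1[code] == pytest.approx(w0[code], rel=1e-9)


class TestConfigRoundTrip:
    def test_packaged_default_matches_registry(self, standards):
        assert load_standards() == standards

    def test_save_load_round_trip(self, tmp_path, standards):
        path = tmp_path / "standards.yaml"
        save_standards(standards, path)
        assert load_standards(path) == standards


class TestStationMetadata:
    def test_sixteen_stations(self):
        stations = load_station_metadata()
        assert [s.code for s in stations] == [f"M{i}" for i in range(1, 17)]

    def test_area_invariant(self):
        for s in load_station_metadata():
            assert s.upstream_km2 >= s.subcatchment_km2 > 0

    def test_outlet_is_maziba_dam(self):
        dam = next(s for s in load_station_metadata() if s.code == "M16")
        assert dam.name == "Maziba Dam"
        assert dam.upstream_km2 == pytest.approx(721.70)
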