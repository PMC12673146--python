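import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aquarisk import (
    WawqiScorer,
    classify_wawqi,
    compute_wawqi,
    quality_rating,
    unit_weights,
)

from conftest import random_sample


def brute_force_wawqi(values, standards):
    """Independent term-by-term Σ QnWn / Σ Wn oracle."""
    wt = unit_weights(standards)
    num = den = 0.0
    for p in standards:
        if not p.in_wawqi or p.code not in values:
            continue
        qn = 100.0 * abs(values[p.code] - p.wawqi_ideal) / abs(
            p.wawqi_standard - p.wawqi_ideal)
        num += qn * wt.weights[p.code]
        den += wt.weights[p.code]
    return num / den


class TestQualityRating:
    def test_value_at_standard_scores_100(self, by_code):
        assert quality_rating(0.2, by_code["NH4_N"]) == pytest.approx(100.0)

    def test_ph_endpoints(self, by_code):
        assert quality_rating(7.0, by_code["PH"]) == 0.0
        assert quality_rating(8.5, by_code["PH"]) == pytest.approx(100.0)
        # below-ideal pH still rates non-negatively (absolute deviation)
        assert quality_rating(5.5, by_code["PH"]) == pytest.approx(100.0)

    def test_oxygen_depleted_station(self, by_code):
        # 100 * (14.6 - 4.31) / (14.6 - 6)
        assert quality_rating(4.31, by_code["DO"]) == pytest.approx(119.6512, abs=1e-3)

    def test_non_member_rejected(self, by_code):
        with pytest.raises(ValueError):
            quality_rating(1.0, by_code["TSS"])


class TestClassification:
    @pytest.mark.parametrize("score,band", [
        (0.0, "Excellent"), (25.0, "Excellent"), (25.0001, "Good"),
        (37.5, "Good"), (50.0, "Good"), (60.0, "Poor"), (75.0, "Poor"),
        (80.0, "Very poor"), (100.0, "Very poor"), (100.01, "Unfit"),
        (1e6, "Unfit"),
    ])
    def test_band_edges(self, score, band):
        assert classify_wawqi(score) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_wawqi(-0.1)


class TestComputeWawqi:
    def ideal_sample(self, standards):
        return {p.code: p.wawqi_ideal for p in standards if p.in_wawqi}

    def standard_sample(self, standards):
        return {p.code: p.wawqi_standard for p in standards if p.in_wawqi}

    def test_all_at_ideal_scores_zero(self, standards):
        res = compute_wawqi(self.ideal_sample(standards), standards)
        assert res.score == pytest.approx(0.0, abs=1e-12)
        assert res.band == "Excellent"

    def test_all_at_standard_scores_100(self, standards):
        res = compute_wawqi(self.standard_sample(standards), standards)
        assert res.score == pytest.approx(100.0, abs=1e-9)
        assert res.band == "Very poor"

    def test_matches_brute_force_oracle(self, rng, standards, by_code):
        for _ in range(200):
            values = random_sample(rng, by_code, "wawqi")
            res = compute_wawqi(values, standards)
            assert res.score == pytest.approx(
                brute_force_wawqi(values, standards), abs=1e-9)

    def test_score_invariant_to_k_rescaling(self, standards, rng, by_code):
        # multiplying all weights by a constant cancels in the weighted mean
        values = random_sample(rng, by_code, "wawqi")
        res = compute_wawqi(values, standards)
        wt = unit_weights(standards)
        num = sum(10.0 * wt.weights[r.parameter] * r.Qn for r in res.ratings)
        den = sum(10.0 * wt.weights[r.parameter] for r in res.ratings)
        assert res.score == pytest.approx(num / den, abs=1e-9)

    def test_weighted_mean_bounds(self, standards, rng, by_code):
        values = random_sample(rng, by_code, "wawqi")
        res = compute_wawqi(values, standards)
        qs = [r.Qn for r in res.ratings]
        assert min(qs) - 1e-9 <= res.score <= max(qs) + 1e-9

    def test_missing_parameter_renormalises(self, standards):
        full = self.standard_sample(standards)
        partial = {k: v for k, v in full.items() if k != "TURB"}
        res = compute_wawqi(partial, standards)
        # every remaining rating is 100, so the renormalised mean stays 100
        assert res.score == pytest.approx(100.0, abs=1e-9)
        assert len(res.ratings) == 12

    def test_strict_mode_errors_on_missing(self, standards):
        partial = {"NH4_N": 0.1}
        with pytest.raises(ValueError, match="missing"):
            compute_wawqi(partial, standards, missing="strict")

    def test_empty_sample_rejected(self, standards):
        with pytest.raises(ValueError):
            compute_wawqi({"TSS": 10.0}, standards)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=5.0),
           st.floats(min_value=0.0, max_value=5.0))
    def test_monotone_in_zero_ideal_parameters(self, standards, v1, v2):
        """Raising any zero-ideal parameter never improves the score."""
        base = {p.code: p.wawqi_standard * 0.5 for p in standards if p.in_wawqi}
        lo, hi = sorted([v1, v2])
        a = dict(base, NH4_N=lo * 0.2)
        b = dict(base, NH4_N=hi * 0.2)
        assert (compute_wawqi(b, standards).score
                >= compute_wawqi(a, standards).score - 1e-12)


class TestScorerEstimator:
    def test_sklearn_contract(self, standards):
        from sklearn.base import clone
        scorer = WawqiScorer(standards=standards, missing="strict")
        params = scorer.get_params()
        assert params["missing"] == "strict"
        clone(scorer)  # get_params/set_params round-trip

    def test_transform_shape_and_agreement(self, rng, standards, by_code):
        rows = [random_sample(rng, by_code, "wawqi") for _ in range(50)]
        X = pd.DataFrame(rows)
        scorer = WawqiScorer(standards=standards).fit()
        out = scorer.transform(X)
        assert out.shape == (50, 1)
        expected = [brute_force_wawqi(r, standards) for r in rows]
        np.testing.assert_allclose(out[:, 0], expected, atol=1e-9)

    def test_unfitted_scorer_raises(self):
        with pytest.raises(AttributeError):
            WawqiScorer().score_samples(pd.DataFrame({"DO": [6.0]}))
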