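"""Midpoint rule, spot aggregation and the mobility/hidden adjustment chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kpsize.errors import EstimationError, SchemaError
from kpsize.mapping import (
    AdjustmentParams,
    HotspotMapping,
    adjust_hidden,
    adjust_mobility,
    aggregate_spots,
    estimate_mobility_params,
    midpoint_estimate,
    pooled_hidden_fraction,
    typology_distribution,
)
from kpsize.util import round_half_up


class TestMidpoint:
    @pytest.mark.parametrize(
        "lo,hi,mid,reported",
        [
            (154, 224, 189.0, 189),
            (2370, 3251, 2810.5, 2811),
            (0, 0, 0.0, 0),
        ],
    )
    def test_midpoint_and_reporting_round(self, lo, hi, mid, reported):
        assert midpoint_estimate(lo, hi) == mid
        assert round_half_up(midpoint_estimate(lo, hi)) == reported

    def test_inverted_range_rejected(self):
        with pytest.raises(EstimationError):
            midpoint_estimate(10, 5)


class TestAggregate:
    def test_two_spots_sum_intervals(self):
        spots = pd.DataFrame(
            {
                "spot_id": ["a", "b"],
                "unit_id": ["u1", "u1"],
                "typology": ["street", "spa"],
                "min_count": [1, 2],
                "max_count": [3, 4],
                "multi_spot": [0.0, 0.0],
                "spots_visited": [1.0, 1.0],
            }
        )
        out = aggregate_spots(spots)
        assert out.loc["u1"].tolist() == [3.0, 5.0, 7.0]

    def test_single_spot_is_identity(self, toy_spots):
        one = toy_spots.iloc[[0]]
        out = aggregate_spots(one)
        assert out.loc["u1", "min"] == 4 and out.loc["u1", "max"] == 6

    def test_midpoint_of_sums_equals_sum_of_midpoints(self, toy_spots):
        out = aggregate_spots(toy_spots)
        mids = (toy_spots["min_count"] + toy_spots["max_count"]) / 2
        assert out["mid"].sum() == pytest.approx(mids.sum())

    def test_duplicate_spot_id_is_double_count_error(self, toy_spots):
        dup = pd.concat([toy_spots, toy_spots.iloc[[0]]], ignore_index=True)
        with pytest.raises(SchemaError, match="duplicate"):
            aggregate_spots(dup)


class TestAdjustments:
    @pytest.mark.parametrize(
        "s1,p1,m1,expected",
        [
            (100, 0.0, 1.0, 100.0),
            (100, 1.0, 2.0, pytest.approx(50.0)),
            (6, 0.206, 2.0, pytest.approx(5.382)),
        ],
    )
    def test_mobility_formula(self, s1, p1, m1, expected):
        assert adjust_mobility(s1, p1, m1) == expected

    @pytest.mark.parametrize(
        "s2,p2,expected",
        [
            (100, 0.0, 100.0),
            (100, 0.5, 200.0),
            # direct evaluation of S2/(1-p2)
            (2563, 0.5825, pytest.approx(2563 / 0.4175)),
        ],
    )
    def test_hidden_formula(self, s2, p2, expected):
        assert adjust_hidden(s2, p2) == expected

    def test_invalid_params_rejected(self):
        with pytest.raises(EstimationError):
            adjust_mobility(10, 0.2, 0.5)
        with pytest.raises(Exception):
            adjust_hidden(10, 1.0)
        with pytest.raises(Exception):
            AdjustmentParams(p1=0.2, m1=0.5, p2=0.1)

    @given(
        s1=st.floats(0, 1e6),
        p1=st.floats(0, 0.999),
        m1=st.floats(1, 20),
        p2=st.floats(0, 0.999),
    )
    def test_adjustment_identities(self, s1, p1, m1, p2):
        """Mobility never inflates, hidden never deflates, and the composed
        map is monotone increasing in the crude count."""
        s2 = adjust_mobility(s1, p1, m1)
        s3 = adjust_hidden(s2, p2)
        assert s2 <= s1 + 1e-9
        assert s3 >= s2 - 1e-9
        bigger = adjust_hidden(adjust_mobility(s1 * 2 + 1, p1, m1), p2)
        assert bigger > s3 - 1e-9

    def test_equality_iff_no_mobility(self):
        assert adjust_mobility(50, 0.0, 3.0) == 50
        assert adjust_mobility(50, 0.3, 1.0) == 50
        assert adjust_mobility(50, 0.3, 1.5) < 50

    def test_aggregate_then_adjust_equals_adjust_then_aggregate(self, toy_spots):
        """With uniform parameters the adjustment is linear, so the order of
        aggregation and adjustment cannot matter."""
        p1, m1, p2 = 0.3, 2.5, 0.4
        agg_first = adjust_hidden(adjust_mobility(aggregate_spots(toy_spots)["mid"].sum(), p1, m1), p2)
        per_spot = adjust_hidden(
            adjust_mobility((toy_spots["min_count"] + toy_spots["max_count"]).to_numpy() / 2, p1, m1),
            p2,
        ).sum()
        assert agg_first == pytest.approx(per_spot)


class TestParams:
    def test_attendance_weighted_p1(self):
        spots = pd.DataFrame(
            {
                "spot_id": ["a", "b"],
                "unit_id": ["u", "u"],
                "typology": ["street", "street"],
                "min_count": [10, 30],
                "max_count": [10, 30],
                "multi_spot": [0.5, 0.0],
                "spots_visited": [2.0, 1.0],
            }
        )
        p1, m1 = estimate_mobility_params(spots)
        assert p1 == pytest.approx((10 * 0.5 + 30 * 0.0) / 40)  # 0.125
        p1u, _ = estimate_mobility_params(spots, weighted=False)
        assert p1u == pytest.approx(0.25)

    def test_m1_weighted_by_mobile_attendance(self):
        spots = pd.DataFrame(
            {
                "spot_id": ["a", "b"],
                "unit_id": ["u", "u"],
                "typology": ["street", "street"],
                "min_count": [10, 20],
                "max_count": [10, 20],
                "multi_spot": [1.0, 0.5],
                "spots_visited": [2.0, 4.0],
            }
        )
        _, m1 = estimate_mobility_params(spots)
        assert m1 == pytest.approx((10 * 1.0 * 2.0 + 20 * 0.5 * 4.0) / (10 * 1.0 + 20 * 0.5))

    def test_survey_size_weighted_hidden_fraction(self):
        p2 = pooled_hidden_fraction({"A": 0.477, "B": 0.736}, {"A": 362, "B": 360})
        assert p2 == pytest.approx((0.477 * 362 + 0.736 * 360) / 722)


class TestTypology:
    def test_all_one_type(self, toy_spots):
        only = toy_spots.assign(typology="street")
        assert typology_distribution(only)["street"] == 100.0

    def test_even_split(self, toy_spots):
        four = toy_spots.iloc[:4].assign(typology=["street", "street", "spa", "spa"])
        dist = typology_distribution(four)
        assert dist["street"] == 50.0 and dist["spa"] == 50.0

    def test_hand_counted_mix(self, toy_spots):
        dist = typology_distribution(toy_spots)
        assert dist["street"] == pytest.approx(40.0)
        assert dist["spa"] == pytest.approx(20.0)
        assert dist["home"] == pytest.approx(20.0)
        assert dist.sum() == pytest.approx(100.0)

    def test_empty_table_rejected(self, toy_spots):
        with pytest.raises(EstimationError):
            typology_distribution(toy_spots.iloc[0:0])


class TestModel:
    def test_regional_hidden_fractions(self, toy_spots):
        params = AdjustmentParams(p1=0.0, m1=1.0, p2={"north": 0.5, "south": 0.0})
        region_of = {"u1": "north", "u2": "south"}
        res = HotspotMapping(toy_spots, params=params, region_of=region_of).fit()
        assert res.fully_adjusted.loc["u1", "mid"] == pytest.approx(
            2 * res.crude.loc["u1", "mid"]
        )
        assert res.fully_adjusted.loc["u2", "mid"] == pytest.approx(res.crude.loc["u2", "mid"])

    def test_summary_reports_all_stages(self, toy_spots):
        res = HotspotMapping(toy_spots, params=AdjustmentParams(p1=0.2, m1=2.0, p2=0.5)).fit()
        text = res.summary()
        assert "crude (S1)" in text and "hidden-adj (S3)" in text
        assert "street" in text
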