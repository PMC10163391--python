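import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapscore import (
    StratifiedRates,
    disparity_ratio,
    innovation_deficit,
    summary_disparity,
    trend,
)
from gapscore.indicators import UndefinedRatioError

rates_strategy = st.dictionaries(
    st.sampled_from(["g1", "g2", "g3", "g4", "g5"]),
    st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
    min_size=2,
    max_size=5,
)


class TestDisparityRatio:
    def test_equal_group_rates_give_unity(self):
        strata = StratifiedRates("mortality", {"a": 10, "b": 10, "c": 10})
        assert disparity_ratio(strata) == 1.0

    def test_worked_case(self):
        # min = 10, mean of the others = (20 + 30) / 2 = 25 -> 2.5
        strata = StratifiedRates("mortality", {"a": 10, "b": 20, "c": 30})
        assert disparity_ratio(strata) == pytest.approx(2.5)

    def test_scale_invariance_worked_case(self):
        strata = StratifiedRates("mortality", {"a": 70, "b": 140, "c": 210})
        assert disparity_ratio(strata) == pytest.approx(2.5)

    def test_favorable_outcome_uses_maximum(self):
        # higher is better: best = 30, mean of others = 15 -> 2.0
        strata = StratifiedRates("screening", {"a": 10, "b": 20, "c": 30}, adverse=False)
        assert disparity_ratio(strata) == pytest.approx(2.0)

    def test_zero_favorable_rate_is_undefined(self):
        strata = StratifiedRates("mortality", {"a": 0, "b": 20})
        with pytest.raises(UndefinedRatioError):
            disparity_ratio(strata)

    @settings(derandomize=True, max_examples=200)
    @given(rates=rates_strategy, scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_at_least_one_and_scale_invariant(self, rates, scale):
        base = disparity_ratio(StratifiedRates("m", rates))
        scaled = disparity_ratio(
            StratifiedRates("m", {k: v * scale for k, v in rates.items()})
        )
        assert base >= 1.0
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_unity_only_for_equal_rates(self):
        assert disparity_ratio(StratifiedRates("m", {"a": 10, "b": 10, "c": 20})) > 1.0

    def test_requires_two_groups_and_a_positive_rate(self):
        with pytest.raises(ValueError):
            StratifiedRates("m", {"a": 1.0})
        with pytest.raises(ValueError):
            StratifiedRates("m", {"a": 0.0, "b": 0.0})


class TestSummaryDisparity:
    def test_single_stratification_is_identity(self):
        strata = {"sex": StratifiedRates("m", {"f": 10, "m": 20})}
        ratio, label = summary_disparity(strata)
        assert ratio == pytest.approx(2.0)
        assert label == "sex"

    def test_maximum_across_stratifications(self):
        strata = {
            "sex": StratifiedRates("m", {"f": 10, "m": 12}),  # 1.2
            "race": StratifiedRates("m", {"a": 10, "b": 20, "c": 30}),  # 2.5
        }
        ratio, label = summary_disparity(strata)
        assert ratio == pytest.approx(2.5)
        assert label == "race"

    def test_all_equal_rate_stratifications(self):
        strata = {
            "sex": StratifiedRates("m", {"f": 7, "m": 7}),
            "age": StratifiedRates("m", {"y": 3, "o": 3}),
        }
        assert summary_disparity(strata)[0] == 1.0

    def test_undefined_ratio_names_stratification(self):
        strata = {"race": StratifiedRates("m", {"a": 0, "b": 5})}
        with pytest.raises(UndefinedRatioError, match="race"):
            summary_disparity(strata)


class TestTrend:
    def test_increase(self):
        t = trend({2015: 100.0, 2019: 150.0}, 2015, 2019)
        assert t.absolute_change == pytest.approx(50.0)
        assert t.relative_change == pytest.approx(0.5)

    def test_constant_series(self):
        t = trend({2015: 80.0, 2019: 80.0}, 2015, 2019)
        assert t.absolute_change == 0.0
        assert t.relative_change == 0.0

    def test_decrease_preserves_sign(self):
        t = trend({2012: 200.0, 2016: 150.0}, 2012, 2016)
        assert t.absolute_change == pytest.approx(-50.0)
        assert t.relative_change == pytest.approx(-0.25)

    def test_missing_year_is_named(self):
        with pytest.raises(KeyError, match="2019"):
            trend({2015: 100.0}, 2015, 2019)

    def test_zero_start_has_no_relative_change(self):
        t = trend({2015: 0.0, 2019: 5.0}, 2015, 2019)
        assert t.absolute_change == 5.0
        assert t.relative_change is None

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=0.1, max_value=1e6),
        b=st.floats(min_value=0.1, max_value=1e6),
    )
    def test_reversal_antisymmetry_in_absolute_change(self, a, b):
        fwd = trend({2015: a, 2019: b}, 2015, 2019)
        rev = trend({2015: b, 2019: a}, 2015, 2019)
        assert fwd.absolute_change == pytest.approx(-rev.absolute_change)


class TestInnovationDeficit:
    @pytest.mark.parametrize(
        "score,expected", [(0.05, 0.95), (0.09, 0.91), (0.1, 0.90), (1.0, 0.0)]
    )
    def test_complement(self, score, expected):
        assert innovation_deficit(score) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(s=st.floats(min_value=0.0, max_value=1.0))
    def test_involution(self, s):
        assert innovation_deficit(innovation_deficit(s)) == pytest.approx(s)

    @pytest.mark.parametrize("bad", [-0.01, 1.01, math.inf])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            innovation_deficit(bad)
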