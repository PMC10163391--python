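"""The derived indicators: disparity summary ratio, trends, innovation deficit.

The disparity summary rate ratio compares the most favorable group's rate
with the average of all other groups (>= 1; 1 means perfect equality), and
is maximised over stratifications.  Trends report absolute and relative
change between two reference years.  The innovation deficit is the
complement 1 - s of an innovation activity score.
"""

from gapscore import (
    StratifiedRates,
    disparity_ratio,
    innovation_deficit,
    summary_disparity,
    trend,
)

rates = StratifiedRates("mortality", {"a": 10.0, "b": 20.0, "c": 30.0}, adverse=True)
print(f"disparity ratio for rates 10/20/30 per 100k: {disparity_ratio(rates)}")
print("  (most favorable group rate 10; mean of the others 25; 25/10 = 2.5)")

ratio, which = summary_disparity(
    {
        "sex": StratifiedRates("mortality", {"female": 10.0, "male": 12.0}),
        "race_ethnicity": rates,
    }
)
print(f"summary disparity across stratifications: {ratio} (attained by {which})")

t = trend({2012: 200.0, 2016: 150.0}, 2012, 2016, metric_id="oop_spending")
print(
    f"OOP spending 2012->2016: absolute change {t.absolute_change}, "
    f"relative change {t.relative_change} (sign preserved)"
)

print(f"innovation deficit of a 0.05 activity score: {innovation_deficit(0.05)}")
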