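"""Rank the published 13-condition pilot score table.

Loads the composite domain scores (public health burden, health care cost,
biomedical product innovation) and overall gap scores reported for the
13-condition pilot, rank-orders them, classifies each score by its
interquartile range (high > Q3, low < Q1, middle otherwise), and prints the
narrative report.  Rank 1 is the largest innovation gap; a line flagged
OPPORTUNITY has low innovation activity despite non-low burden or cost.
"""

from gapscore import narrative_report, rank_pilot

result = rank_pilot()
print(narrative_report(result.results))

overall = result.tier_assignments["overall"]
print(
    f"\nOverall-gap quartiles: Q1={overall.q1:.3f}, Q3={overall.q3:.3f} "
    "(scores above Q3 are high-gap, below Q1 low-gap)"
)
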