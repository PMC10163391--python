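# gapscore

Health-priority analysts and research funders often steer investment by a
single metric (usually mortality), which can leave high-burden, high-cost
conditions under-served by biomedical product innovation.  `gapscore`
implements a data-driven framework that scores medical conditions on three
domains — **public health burden** (mortality, YLD, prevalence, disparity,
and their trends), **health care cost** (total, public, and out-of-pocket
spending and their trends), and **biomedical product innovation** (patents,
federal and private investment, venture capital, clinical trials, FDA
approvals) — and integrates the three domain scores into a single **overall
gap score** that is high where innovation activity lags burden and cost.

## Method

The integration engine is TOPSIS (Technique for Order of Preference by
Similarity to Ideal Solution).  Given an alternatives × criteria matrix
*x<sub>ij</sub>* with direction flags and positive weights *w<sub>j</sub>*:

1. normalise each column, by default *r<sub>ij</sub> = x<sub>ij</sub> /
   √Σ<sub>i</sub> x<sub>ij</sub>²* (a min–max variant is available);
2. weight: *v<sub>ij</sub> = ŵ<sub>j</sub> r<sub>ij</sub>* with
   *ŵ<sub>j</sub> = w<sub>j</sub> / Σ w*;
3. form the ideal point *A⁺* (lowest burden and cost, highest innovation on
   every criterion) and the anti-ideal *A⁻* (the componentwise opposite);
4. compute Euclidean separations *d<sub>i</sub>⁺ = ‖v<sub>i</sub> − A⁺‖* and
   *d<sub>i</sub>⁻ = ‖v<sub>i</sub> − A⁻‖*;
5. the gap score is *G<sub>i</sub> = d<sub>i</sub>⁺ / (d<sub>i</sub>⁺ +
   d<sub>i</sub>⁻)* ∈ [0, 1] — 0 at the ideal, 1 at the anti-ideal.

Domain scores are TOPSIS runs over each domain's criteria (cross-sectional
values, longitudinal trends, and — for burden — the Healthy People 2020
disparity summary rate ratio).  The overall gap is a second TOPSIS run over
the three domain scores with equal domain weights; burden and cost enter
gap-increasing, innovation gap-decreasing.  Conditions are rank-ordered by
overall gap and classified high/middle/low by the interquartile range of
each score; conditions with a low innovation tier but non-low burden or cost
are flagged as innovation-investment opportunities.

## Worked example

The package ships the published 13-condition pilot score table and can rank
and tier it directly:

```python
from gapscore import narrative_report, rank_pilot

result = rank_pilot()
print(narrative_report(result.results))
```

prints (first and last lines):

```
 1. Diabetes mellitus: overall gap 0.61 (high); tiers: burden middle, cost high,
    innovation high; dominant factor: health care cost; - [high health care cost
    despite high innovation activity (cost-innovation paradox; not an innovation
    opportunity)]
...
 6. Chronic kidney disease: overall gap 0.36 (middle); tiers: burden middle, cost
    middle, innovation low; dominant factor: low biomedical product innovation;
    OPPORTUNITY [low innovation activity relative to middle public health burden
    and middle health care cost]
...
13. Lower respiratory infections: overall gap 0.27 (low); tiers: burden low,
    cost low, innovation middle; dominant factor: low biomedical product
    innovation; -
```

Diabetes tops the ranking (overall gap 0.61) with cost as the dominant
factor — the paradox case where high spending coexists with high innovation
activity — while chronic kidney disease, COPD, and cirrhosis are flagged as
innovation opportunities: their innovation scores (0.05, 0.09, 0.10,
i.e. deficits of 0.95, 0.91, 0.90) lag their middle burden and cost tiers.

The `examples/` directory holds short narrative scripts for each capability
(pilot ranking, synthetic simulation + full pipeline, derived indicators),
and a thin CLI wraps the same library calls:

```sh
gapscore simulate --out sim --seed 42
gapscore run --metrics sim/metrics.csv --out results
gapscore report results/results.json
```

## Synthetic studies

Because the raw metric tables behind the pilot composites were never
deposited, `gapscore.synthetic` generates full metric tables with known
structure: log-normal rates, spending totals, and Poisson activity counts
for 13 conditions, stratified mortality for the disparity ratio, and
optionally a *planted* gap condition (high burden and cost, low innovation)
whose recovery at rank 1 calibrates the whole pipeline.

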