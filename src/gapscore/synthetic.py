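"""Synthetic metric tables with known, plantable gap structure.

Real inputs to the framework are positive, right-skewed quantities: rates
per 100 000 (mortality, YLD, prevalence), dollar totals (public, OOP, total
spending), and activity counts (patents, grants, venture deals, trials,
approvals).  The generator emulates them with a log-normal value model:

    log value ~ mu_metric + b(condition, metric) + drift * (year - y0) + noise

where ``b`` is a per-condition, per-metric log-normal random effect that
creates stable between-condition differences, ``drift`` a small per-series
linear slope (so trend criteria are informative), and ``noise`` year-to-year
jitter.  Count metrics are drawn Poisson with the log-normal value as rate,
keeping them integral.  Stratified mortality rates (sex, age,
race/ethnicity) are emitted for the disparity summary ratio with a
configurable between-group rate ratio.

Two conditions can be *planted*:

* ``planted_gap`` — shifted up on every burden and cost metric and down on
  every innovation metric: a known rank-1 gap condition;
* ``planted_paradox`` — shifted up on cost **and** innovation: the
  high-cost/high-innovation paradox case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    Condition,
    MetricDefinition,
    MetricTable,
    OBSERVATION_COLUMNS,
    default_direction,
)
from .io_config import RunConfig
from .pipeline import score_table

#: metric_id -> (domain, log-location of the value model, units, is_count)
#: Innovation metrics span six categories: patents, federal investment,
#: private investment, venture capital, clinical trials, FDA approvals.
METRIC_MODEL: dict[str, tuple[str, float, str, bool]] = {
    # public health burden (rates per 100 000)
    "mortality": ("burden", np.log(50.0), "per 100000", False),
    "yld": ("burden", np.log(300.0), "per 100000", False),
    "prevalence": ("burden", np.log(5000.0), "per 100000", False),
    # health care cost (billions of dollars)
    "total_spending": ("cost", np.log(60.0), "billion USD", False),
    "public_spending": ("cost", np.log(30.0), "billion USD", False),
    "oop_spending": ("cost", np.log(12.0), "billion USD", False),
    # innovation: patents
    "patents_filed": ("innovation", np.log(600.0), "count", True),
    "patents_granted": ("innovation", np.log(300.0), "count", True),
    # innovation: federal investment
    "nih_funding": ("innovation", np.log(400.0), "million USD", False),
    "nih_projects": ("innovation", np.log(200.0), "count", True),
    # innovation: private investment
    "private_investment": ("innovation", np.log(1000.0), "million USD", False),
    "private_deals": ("innovation", np.log(100.0), "count", True),
    # innovation: venture capital
    "vc_early_funding": ("innovation", np.log(100.0), "million USD", False),
    "vc_late_funding": ("innovation", np.log(150.0), "million USD", False),
    "vc_early_deals": ("innovation", np.log(40.0), "count", True),
    "vc_late_deals": ("innovation", np.log(25.0), "count", True),
    # innovation: clinical trials
    "trials_started": ("innovation", np.log(150.0), "count", True),
    "trials_completed": ("innovation", np.log(120.0), "count", True),
    "trials_results_posted": ("innovation", np.log(60.0), "count", True),
    # innovation: FDA approvals
    "fda_drug_approvals": ("innovation", np.log(6.0), "count", True),
    "fda_device_approvals": ("innovation", np.log(9.0), "count", True),
    "fda_expedited_approvals": ("innovation", np.log(3.0), "count", True),
}

STRATIFICATIONS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "age": ("0-17", "18-64", "65plus"),
    "race_ethnicity": ("white", "black", "hispanic", "aian"),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of one synthetic study.

    ``gap_effect`` and ``paradox_effect`` are expressed in units of the
    between-condition log spread ``condition_sigma``; the default of 4
    separates the planted condition from the population by four standard
    deviations on every affected metric.
    """

    n_conditions: int = 13
    burden_years: tuple[int, int] = (2015, 2019)
    cost_years: tuple[int, int] = (2012, 2016)
    innovation_years: tuple[int, int] = (2015, 2019)
    condition_sigma: float = 0.5
    noise_sigma: float = 0.2
    drift_mean: float = 0.03
    drift_sigma: float = 0.05
    between_group_ratio: float = 1.5
    group_noise_sigma: float = 0.05
    planted_gap: Optional[str] = None
    planted_paradox: Optional[str] = None
    gap_effect: float = 4.0
    paradox_effect: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 4:
            raise ValueError("n_conditions must be >= 4")
        ids = set(self.condition_ids())
        for planted in (self.planted_gap, self.planted_paradox):
            if planted is not None and planted not in ids:
                raise ValueError(f"planted condition {planted!r} not in roster {sorted(ids)}")
        if self.planted_gap is not None and self.planted_gap == self.planted_paradox:
            raise ValueError("planted_gap and planted_paradox must be distinct")
        if self.between_group_ratio < 1:
            raise ValueError("between_group_ratio must be >= 1")

    def condition_ids(self) -> list[str]:
        return [f"c{i + 1:02d}" for i in range(self.n_conditions)]


def _planted_shift(spec: SyntheticSpec, cid: str, domain: str) -> float:
    """Log-space location shift for planted conditions."""
    shift = 0.0
    if cid == spec.planted_gap:
        if domain in ("burden", "cost"):
            shift += spec.gap_effect * spec.condition_sigma
        else:
            shift -= spec.gap_effect * spec.condition_sigma
    if cid == spec.planted_paradox and domain in ("cost", "innovation"):
        shift += spec.paradox_effect * spec.condition_sigma
    return shift


def generate(spec: SyntheticSpec) -> MetricTable:
    """Draw one complete metric table from the spec; same seed, same table."""
    rng = np.random.default_rng(spec.seed)
    cids = spec.condition_ids()
    conditions = {
        cid: Condition(condition_id=cid, name=f"Condition {cid[1:]}") for cid in cids
    }
    definitions = {
        mid: MetricDefinition(
            metric_id=mid,
            domain=domain,
            direction=default_direction(domain),
            units=units,
        )
        for mid, (domain, _, units, _) in METRIC_MODEL.items()
    }
    windows = {
        "burden": spec.burden_years,
        "cost": spec.cost_years,
        "innovation": spec.innovation_years,
    }

    rows: list[tuple] = []
    mortality_ref: dict[str, float] = {}
    for mid, (domain, mu, _, is_count) in METRIC_MODEL.items():
        y0, y1 = windows[domain]
        years = list(range(y0, y1 + 1))
        for cid in cids:
            b = rng.normal(0.0, spec.condition_sigma) + _planted_shift(spec, cid, domain)
            drift = rng.normal(spec.drift_mean, spec.drift_sigma)
            for year in years:
                logv = (
                    mu
                    + b
                    + drift * (year - y0)
                    + rng.normal(0.0, spec.noise_sigma)
                )
                value = float(rng.poisson(np.exp(logv))) if is_count else float(np.exp(logv))
                rows.append((cid, mid, year, None, value))
                if mid == "mortality" and year == y1:
                    # anchor for the stratified rates emitted below
                    mortality_ref[cid] = value

    # stratified mortality at the burden reference year
    ref_year = spec.burden_years[1]
    ratio = spec.between_group_ratio
    for cid in cids:
        base = mortality_ref[cid]
        for strat, groups in STRATIFICATIONS.items():
            favorable = groups[int(rng.integers(len(groups)))]
            for group in groups:
                if group == favorable:
                    rate = base
                else:
                    rate = base * ratio * float(
                        np.exp(rng.normal(0.0, spec.group_noise_sigma))
                    )
                rows.append((cid, "mortality", ref_year, f"{strat}:{group}", rate))

    data = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    return MetricTable(conditions=conditions, definitions=definitions, data=data)


@dataclass
class RecoveryResult:
    """Outcome of a planted-gap rank-recovery experiment."""

    fraction: float
    ranks: list[int]
    n_replicates: int


def planted_rank_recovery(
    spec: SyntheticSpec,
    n_replicates: int = 20,
    config: Optional[RunConfig] = None,
    target: Optional[str] = None,
) -> RecoveryResult:
    """Fraction of replicates in which a condition is ranked 1 overall.

    Each replicate regenerates the table with a fresh seed (``spec.seed + i``)
    and runs the full pipeline.  ``target`` defaults to the planted-gap
    condition; pass any roster id to measure a null (exchangeable) condition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    target = target or spec.planted_gap
    if target is None:
        raise ValueError("spec has no planted_gap and no explicit target")
    ranks: list[int] = []
    for i in range(n_replicates):
        rep = replace(spec, seed=spec.seed + i)
        result = score_table(generate(rep), config)
        rank = next(r.rank for r in result.results if r.condition_id == target)
        ranks.append(rank)
    fraction = sum(1 for r in ranks if r == 1) / n_replicates
    return RecoveryResult(fraction=fraction, ranks=ranks, n_replicates=n_replicates)
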