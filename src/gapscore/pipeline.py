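"""End-to-end scoring: pilot selection, domain scores, overall gap, tiers.

The pipeline mirrors the framework's stages:

1. **Pilot selection** — union of the top-k condition lists by mortality,
   prevalence, and years lived with disability (YLD), duplicates removed.
2. **Domain scores** — one TOPSIS run per domain over that domain's
   cross-sectional metrics, longitudinal trend criteria, and (for burden)
   the disparity summary rate ratio.  Every domain score is oriented so that
   *more of the domain quantity* means a higher score: high burden, high
   cost, or high innovation activity all score near 1 within their domain.
3. **Overall gap** — a second TOPSIS run over the three domain scores with
   equal domain weights; burden and cost enter gap-increasing, innovation
   gap-decreasing.  (A ``flat`` mode pools all raw criteria into a single
   matrix instead, with each domain's criteria sharing its weight mass.)
4. **IQR tiers** — scores above the third quartile are ``high``, below the
   first quartile ``low``, otherwise ``middle``.
5. **Opportunity identification** — conditions whose innovation tier is low
   while burden or cost is not low are flagged as innovation-investment
   opportunities, with a reason string naming the contributing domains.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    DOMAINS,
    GAP_DECREASING,
    GAP_INCREASING,
    GapResult,
    MetricTable,
)
from .indicators import StratifiedRates, UndefinedRatioError, summary_disparity, trend
from .io_config import RunConfig
from .mcdm import DecisionMatrix, TopsisTrace, gap_scores

logger = logging.getLogger("gapscore")

#: Human-readable domain labels used in reason strings.
DOMAIN_LABELS = {
    "burden": "public health burden",
    "cost": "health care cost",
    "innovation": "biomedical product innovation",
}


@dataclass
class DomainScoreSet:
    """Per-condition scores for one domain, with provenance."""

    domain: str
    scores: dict[str, float]
    metric_ids: list[str]
    reference_years: dict[str, object]
    trace: Optional[TopsisTrace] = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class TierAssignment:
    """High/middle/low classification of a score set by its IQR."""

    kind: str
    tiers: dict[str, str]
    q1: float
    q3: float


@dataclass
class PipelineResult:
    """Everything a full run produces."""

    results: list[GapResult]
    domain_scores: dict[str, DomainScoreSet]
    tier_assignments: dict[str, TierAssignment]
    warnings: list[str] = field(default_factory=list)


def select_pilot_conditions(
    burden_table: MetricTable,
    k: int = 10,
    ranking_metrics: tuple[str, ...] = ("mortality", "prevalence", "yld"),
    year: Optional[int] = None,
) -> list[str]:
    """Deduplicated union of the top-k condition lists per ranking metric.

    Conditions are ordered by first appearance across the lists (mortality
    list first, then prevalence, then YLD).  If fewer than ``k`` conditions
    carry a metric, all of them are used and a warning is logged.
    """
    df = burden_table.data
    df = df[df["stratum"].isna()]
    if year is not None:
        df = df[df["year"] == year]
    selected: list[str] = []
    for metric in ranking_metrics:
        sub = df[df["metric_id"] == metric]
        series = sub.groupby("condition_id")["value"].mean()
        if len(series) < k:
            logger.warning(
                "metric %r: only %d conditions available (top-%d requested)",
                metric,
                len(series),
                k,
            )
        # descending value, condition id as deterministic tie-break
        top = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        for cid, _ in top:
            if cid not in selected:
                selected.append(cid)
    return selected


def _series_for(df: pd.DataFrame, cid: str, metric: str) -> dict[int, float]:
    sub = df[
        (df["condition_id"] == cid) & (df["metric_id"] == metric) & df["stratum"].isna()
    ]
    return dict(zip(sub["year"].astype(int), sub["value"].astype(float)))


def _disparity_for(
    df: pd.DataFrame, cid: str, metric: str, year: Optional[int]
) -> Optional[float]:
    """Max disparity summary ratio over stratifications, or None if absent."""
    sub = df[
        (df["condition_id"] == cid)
        & (df["metric_id"] == metric)
        & df["stratum"].notna()
    ]
    if year is not None:
        sub = sub[sub["year"] == year]
    if sub.empty:
        return None
    per_strat: dict[str, dict[str, float]] = {}
    for row in sub.itertuples(index=False):
        strat, _, group = str(row.stratum).partition(":")
        per_strat.setdefault(strat, {})[group or strat] = float(row.value)
    rates = {
        label: StratifiedRates(outcome=metric, rates=groups, adverse=True)
        for label, groups in per_strat.items()
        if len(groups) >= 2 and any(v > 0 for v in groups.values())
    }
    if not rates:
        return None
    ratio, _ = summary_disparity(rates)
    return ratio


def build_domain_matrix(
    table: MetricTable, domain: str, config: RunConfig
) -> tuple[DecisionMatrix, list[str]]:
    """Assemble the within-domain decision matrix.

    Criteria are, per metric: the cross-sectional value at the domain's
    reference year (or the mean over the trend window when the reference year
    is None, as for innovation), a trend criterion over the domain's window,
    and — for metrics with stratified observations — the disparity summary
    ratio.  All criteria are oriented gap-increasing within the domain, so
    the domain score measures "how much of this domain's quantity" a
    condition carries.  Negative trend columns are shifted to be nonnegative;
    all-zero columns are dropped with a warning.
    """
    metrics = sorted(m.metric_id for m in table.metrics_in_domain(domain))
    if not metrics:
        raise ValueError(f"no metrics registered for domain {domain!r}")
    cids = sorted(table.conditions)
    df = table.data
    ref_year = config.reference_years.get(domain)
    start, end = config.trend_windows.get(domain, (None, None))
    scale = config.trend_scale.get(domain, "relative")

    columns: dict[str, list[Optional[float]]] = {}
    warnings: list[str] = []
    for metric in metrics:
        xs_col: list[Optional[float]] = []
        tr_col: list[Optional[float]] = []
        disp_col: list[Optional[float]] = []
        for cid in cids:
            series = _series_for(df, cid, metric)
            if ref_year is not None:
                xs_col.append(series.get(ref_year))
            elif series and start is not None:
                window = [v for y, v in series.items() if start <= y <= end]
                xs_col.append(float(np.mean(window)) if window else None)
            else:
                xs_col.append(float(np.mean(list(series.values()))) if series else None)
            if start is not None and start in series and end in series:
                t = trend(series, start, end, metric_id=metric)
                if scale == "relative":
                    tr_col.append(t.relative_change)
                else:
                    tr_col.append(t.absolute_change)
            else:
                tr_col.append(None)
            if domain == "burden":
                try:
                    disp_col.append(_disparity_for(df, cid, metric, ref_year))
                except UndefinedRatioError as exc:
                    warnings.append(f"{cid}/{metric}: {exc}")
                    disp_col.append(None)
        columns[metric] = xs_col
        if any(v is not None for v in tr_col):
            columns[f"{metric}__trend"] = tr_col
        if domain == "burden" and any(v is not None for v in disp_col):
            columns[f"{metric}__disparity"] = disp_col

    mat = pd.DataFrame(columns, index=cids, dtype=float)

    # missing-value policy
    missing = mat.isna()
    if missing.any().any():
        policy = config.missing_policy
        for col in mat.columns[missing.any()]:
            who = list(mat.index[missing[col]])
            warnings.append(
                f"domain {domain!r}: criterion {col!r} missing for {who}; "
                f"policy={policy}"
            )
        if policy == "zero":
            mat = mat.fillna(0.0)
        elif policy == "mean_impute":
            mat = mat.fillna(mat.mean())
        else:  # drop_criterion
            mat = mat.dropna(axis=1)
            if mat.shape[1] == 0:
                raise ValueError(
                    f"domain {domain!r}: every criterion dropped by missing policy"
                )

    # trends may be negative; shift each such column so its minimum is 0
    for col in mat.columns:
        lo = mat[col].min()
        if lo < 0:
            mat[col] = mat[col] - lo
            warnings.append(
                f"domain {domain!r}: criterion {col!r} shifted by {-lo:.6g} "
                "to be nonnegative"
            )

    # all-zero columns carry no information and break vector normalisation
    zero_cols = [c for c in mat.columns if (mat[c] == 0).all()]
    if zero_cols:
        warnings.append(f"domain {domain!r}: dropping all-zero criteria {zero_cols}")
        mat = mat.drop(columns=zero_cols)
    if mat.shape[1] == 0:
        raise ValueError(f"domain {domain!r}: no usable criteria remain")

    weights = np.array(
        [config.within_domain_weights.get(c, 1.0) for c in mat.columns], dtype=float
    )
    matrix = DecisionMatrix(
        alternatives=cids,
        criteria=list(mat.columns),
        values=mat.to_numpy(),
        directions=[GAP_INCREASING] * mat.shape[1],
        weights=weights,
    )
    for w in warnings:
        # routine rescaling notes at debug; data-loss events at warning
        level = logging.DEBUG if "shifted by" in w else logging.WARNING
        logger.log(level, "%s", w)
    return matrix, warnings


def domain_score(table: MetricTable, domain: str, config: RunConfig) -> DomainScoreSet:
    """TOPSIS score of every condition within one domain (in [0, 1])."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    matrix, warnings = build_domain_matrix(table, domain, config)
    trace = gap_scores(matrix, normalization=config.normalization)
    return DomainScoreSet(
        domain=domain,
        scores=dict(zip(matrix.alternatives, (float(g) for g in trace.gap))),
        metric_ids=list(matrix.criteria),
        reference_years={
            "reference_year": config.reference_years.get(domain),
            "trend_window": list(config.trend_windows.get(domain, ())),
        },
        trace=trace,
        warnings=warnings,
    )


def overall_gap(
    domain_scores: dict[str, DomainScoreSet],
    config: RunConfig,
    names: Optional[dict[str, str]] = None,
    domain_matrices: Optional[dict[str, DecisionMatrix]] = None,
) -> list[GapResult]:
    """Integrate the three domain scores into overall gap scores and ranks.

    Hierarchical mode (default) runs TOPSIS on the (burden, cost, innovation)
    score triples with directions (gap-increasing, gap-increasing,
    gap-decreasing) and the configured domain weights.  Flat mode pools the
    raw per-domain matrices into one, each domain's criteria sharing that
    domain's weight mass.  Rank 1 is the largest gap; ties break on condition
    name ascending.
    """
    missing_domains = [d for d in DOMAINS if d not in domain_scores]
    if missing_domains:
        raise ValueError(f"domain scores missing for: {missing_domains}")
    cid_sets = {d: set(s.scores) for d, s in domain_scores.items()}
    common = set.intersection(*cid_sets.values())
    union = set.union(*cid_sets.values())
    if common != union:
        raise ValueError(
            f"condition sets differ across domains; missing somewhere: "
            f"{sorted(union - common)}"
        )
    cids = sorted(common)
    if len(cids) < 2:
        raise ValueError("need at least 2 conditions for relative ranking")

    if config.aggregation_mode == "hierarchical" or domain_matrices is None:
        values = np.array(
            [[domain_scores[d].scores[cid] for d in DOMAINS] for cid in cids]
        )
        matrix = DecisionMatrix(
            alternatives=cids,
            criteria=list(DOMAINS),
            values=values,
            directions=[GAP_INCREASING, GAP_INCREASING, GAP_DECREASING],
            weights=np.array([config.domain_weights[d] for d in DOMAINS]),
        )
        trace = gap_scores(matrix, normalization=config.normalization)
    else:  # flat
        blocks, criteria, directions, weights = [], [], [], []
        for d in DOMAINS:
            m = domain_matrices[d]
            order = [m.alternatives.index(cid) for cid in cids]
            blocks.append(m.values[order])
            criteria.extend(f"{d}:{c}" for c in m.criteria)
            direction = GAP_DECREASING if d == "innovation" else GAP_INCREASING
            directions.extend([direction] * len(m.criteria))
            # domain's criteria share the domain's weight mass
            w = m.weights / m.weights.sum() * config.domain_weights[d]
            weights.extend(w.tolist())
        matrix = DecisionMatrix(
            alternatives=cids,
            criteria=criteria,
            values=np.hstack(blocks),
            directions=directions,
            weights=np.array(weights),
        )
        trace = gap_scores(matrix, normalization=config.normalization)

    names = names or {}
    gap = dict(zip(cids, (float(g) for g in trace.gap)))
    order = sorted(cids, key=lambda c: (-gap[c], names.get(c, c)))
    ranks = {cid: i + 1 for i, cid in enumerate(order)}
    return [
        GapResult(
            condition_id=cid,
            name=names.get(cid, cid),
            domain_scores={d: float(domain_scores[d].scores[cid]) for d in DOMAINS},
            overall_gap=gap[cid],
            rank=ranks[cid],
        )
        for cid in cids
    ]


def iqr_tiers(
    scores: dict[str, float], quantile_convention: str = "linear", kind: str = "overall"
) -> TierAssignment:
    """Classify scores as high (> Q3), low (< Q1), or middle.

    Quartiles use the configured convention (numpy method name; default
    ``linear`` interpolation between order statistics).  Boundary values
    (exactly Q1 or Q3) are middle: the inequalities are strict.
    """
    if len(scores) < 4:
        raise ValueError(f"need >= 4 scores for quartile tiers, got {len(scores)}")
    values = np.array(list(scores.values()), dtype=float)
    q1, q3 = np.percentile(values, [25, 75], method=quantile_convention)
    tiers = {
        key: "high" if s > q3 else ("low" if s < q1 else "middle")
        for key, s in scores.items()
    }
    return TierAssignment(kind=kind, tiers=tiers, q1=float(q1), q3=float(q3))


def identify_opportunities(
    results: list[GapResult],
) -> list[tuple[str, str]]:
    """Flag innovation-investment opportunities from tier combinations.

    A condition is an opportunity when its innovation tier is low while its
    burden or cost tier is middle or high: innovation activity lags the need.
    A high-cost/high-innovation condition is the paradox case — its costs may
    themselves be driven by innovation — and is annotated but not flagged.
    Mutates ``opportunity_flag`` and ``reason`` in place and returns
    (condition_id, reason) pairs for the flagged conditions.
    """
    flagged: list[tuple[str, str]] = []
    for r in results:
        tiers = r.tiers
        if not tiers:
            continue
        innov = tiers.get("innovation")
        contributing = [
            d for d in ("burden", "cost") if tiers.get(d) in ("high", "middle")
        ]
        if innov == "low" and contributing:
            parts = " and ".join(f"{tiers[d]} {DOMAIN_LABELS[d]}" for d in contributing)
            r.reason = f"low innovation activity relative to {parts}"
            r.opportunity_flag = True
            flagged.append((r.condition_id, r.reason))
        elif innov == "high" and tiers.get("cost") == "high":
            r.reason = (
                "high health care cost despite high innovation activity "
                "(cost-innovation paradox; not an innovation opportunity)"
            )
        elif not r.reason:
            r.reason = ""
    return flagged


def dominant_domain(result: GapResult, tol: float = 1e-9) -> str:
    """Which domain contributes most to the gap: burden, cost, or innovation.

    Candidates are the burden score, the cost score, and the innovation
    deficit (1 - innovation score).  Returns ``"none"`` when all candidates
    tie within ``tol``.
    """
    candidates = {
        "burden": result.domain_scores["burden"],
        "cost": result.domain_scores["cost"],
        "innovation": 1.0 - result.domain_scores["innovation"],
    }
    lo, hi = min(candidates.values()), max(candidates.values())
    if hi - lo <= tol:
        return "none"
    return max(sorted(candidates), key=lambda k: candidates[k])


def _attach_tiers(
    results: list[GapResult], config: RunConfig
) -> tuple[dict[str, TierAssignment], list[str]]:
    warnings: list[str] = []
    assignments: dict[str, TierAssignment] = {}
    if len(results) < 4:
        warnings.append("fewer than 4 conditions: quartile tiers skipped")
        return assignments, warnings
    for kind in (*DOMAINS, "overall"):
        scores = {
            r.condition_id: (
                r.overall_gap if kind == "overall" else r.domain_scores[kind]
            )
            for r in results
        }
        assignments[kind] = iqr_tiers(scores, config.quantile_convention, kind=kind)
    for r in results:
        r.tiers = {k: a.tiers[r.condition_id] for k, a in assignments.items()}
    return assignments, warnings


def score_table(table: MetricTable, config: Optional[RunConfig] = None) -> PipelineResult:
    """Run the full framework on a metric table."""
    config = config or RunConfig()
    domain_scores: dict[str, DomainScoreSet] = {}
    matrices: dict[str, DecisionMatrix] = {}
    warnings: list[str] = []
    for domain in DOMAINS:
        matrix, w = build_domain_matrix(table, domain, config)
        trace = gap_scores(matrix, normalization=config.normalization)
        domain_scores[domain] = DomainScoreSet(
            domain=domain,
            scores=dict(zip(matrix.alternatives, (float(g) for g in trace.gap))),
            metric_ids=list(matrix.criteria),
            reference_years={
                "reference_year": config.reference_years.get(domain),
                "trend_window": list(config.trend_windows.get(domain, ())),
            },
            trace=trace,
            warnings=w,
        )
        matrices[domain] = matrix
        warnings.extend(w)

    names = {cid: c.name for cid, c in table.conditions.items()}
    results = overall_gap(
        domain_scores, config, names=names, domain_matrices=matrices
    )
    assignments, w = _attach_tiers(results, config)
    warnings.extend(w)
    identify_opportunities(results)
    return PipelineResult(
        results=results,
        domain_scores=domain_scores,
        tier_assignments=assignments,
        warnings=warnings,
    )


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


def results_from_scores(
    scores: pd.DataFrame, config: Optional[RunConfig] = None
) -> PipelineResult:
    """Report-only entry point: ingest precomputed domain/overall scores.

    ``scores`` needs columns ``condition`` (or ``condition_id``),
    ``burden_score``, ``cost_score``, ``innovation_score``, and optionally
    ``overall_gap``.  If the overall gap is absent it is recomputed
    hierarchically from the domain scores; otherwise the given values are
    ranked as-is.  Tiers and opportunity flags are always recomputed.
    """
    config = config or RunConfig()
    required = {"burden_score", "cost_score", "innovation_score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table missing columns: {sorted(missing)}")
    df = scores.copy()
    if "condition" not in df.columns:
        df["condition"] = df["condition_id"]
    if "condition_id" not in df.columns:
        df["condition_id"] = df["condition"].map(_slug)

    domain_scores = {
        d: DomainScoreSet(
            domain=d,
            scores=dict(zip(df["condition_id"], df[f"{col}_score"].astype(float))),
            metric_ids=[f"{col}_score"],
            reference_years={},
        )
        for d, col in (("burden", "burden"), ("cost", "cost"), ("innovation", "innovation"))
    }
    names = dict(zip(df["condition_id"], df["condition"]))

    if "overall_gap" in df.columns:
        gap = dict(zip(df["condition_id"], df["overall_gap"].astype(float)))
        order = sorted(gap, key=lambda c: (-gap[c], names.get(c, c)))
        ranks = {cid: i + 1 for i, cid in enumerate(order)}
        results = [
            GapResult(
                condition_id=cid,
                name=names[cid],
                domain_scores={d: domain_scores[d].scores[cid] for d in DOMAINS},
                overall_gap=gap[cid],
                rank=ranks[cid],
            )
            for cid in df["condition_id"]
        ]
    else:
        results = overall_gap(domain_scores, config, names=names)

    assignments, warnings = _attach_tiers(results, config)
    identify_opportunities(results)
    return PipelineResult(
        results=results,
        domain_scores=domain_scores,
        tier_assignments=assignments,
        warnings=warnings,
    )
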