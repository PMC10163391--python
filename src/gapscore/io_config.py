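"""Readers and writers: metric CSV tables, YAML run configuration, results.

The metrics CSV is long format, UTF-8, comma-separated, with a required
header::

    condition_id,condition_name,domain,metric_id,year,stratum,value,units

An empty ``stratum`` cell means "no stratum".  Values round-trip at full
float precision; rounding happens only in the human-readable scores report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .data_model import (
    DOMAINS,
    Condition,
    GapResult,
    MetricDefinition,
    MetricTable,
    default_direction,
)

CSV_COLUMNS = (
    "condition_id",
    "condition_name",
    "domain",
    "metric_id",
    "year",
    "stratum",
    "value",
    "units",
)

MISSING_POLICIES = ("zero", "drop_criterion", "mean_impute")
AGGREGATION_MODES = ("hierarchical", "flat")


class MetricsFormatError(ValueError):
    """Malformed metrics CSV: missing columns or unparseable records."""


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Every knob of a scoring run, with total defaults (empty config is valid).

    domain_weights
        Relative weight of each domain in the overall gap (all 1 by default:
        equal weighting); only ratios matter.
    within_domain_weights
        Optional per-metric weights inside a domain matrix (equal by default).
    normalization
        ``vector`` (root-sum-square, the classic TOPSIS choice) or ``minmax``.
    aggregation_mode
        ``hierarchical`` — overall TOPSIS on the three domain scores;
        ``flat`` — one matrix pooling all metrics, each domain's metrics
        sharing that domain's weight mass.
    missing_policy
        How a condition with no value for a criterion is handled: ``zero``
        (default; mirrors "no recorded deaths"), ``drop_criterion``, or
        ``mean_impute``.
    reference_years / trend_windows
        Per-domain cross-sectional reference year (None = mean over the trend
        window, used for innovation) and (start, end) trend years.
    trend_scale
        Whether a domain's trend criteria enter as relative or absolute
        change (relative for rates, absolute for dollar totals by default).
    """

    domain_weights: dict[str, float] = field(
        default_factory=lambda: {d: 1.0 for d in DOMAINS}
    )
    within_domain_weights: dict[str, float] = field(default_factory=dict)
    normalization: str = "vector"
    aggregation_mode: str = "hierarchical"
    missing_policy: str = "zero"
    quantile_convention: str = "linear"
    seed: Optional[int] = None
    reference_years: dict[str, Optional[int]] = field(
        default_factory=lambda: {"burden": 2019, "cost": 2016, "innovation": None}
    )
    trend_windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "burden": (2015, 2019),
            "cost": (2012, 2016),
            "innovation": (2015, 2019),
        }
    )
    trend_scale: dict[str, str] = field(
        default_factory=lambda: {
            "burden": "relative",
            "cost": "absolute",
            "innovation": "relative",
        }
    )
    display_decimals: int = 2

    def __post_init__(self) -> None:
        for domain, w in self.domain_weights.items():
            if w <= 0:
                raise ConfigError(f"domain weight for {domain!r} must be > 0, got {w}")
        for mid, w in self.within_domain_weights.items():
            if w <= 0:
                raise ConfigError(f"metric weight for {mid!r} must be > 0, got {w}")
        if self.normalization not in ("vector", "minmax"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.aggregation_mode not in AGGREGATION_MODES:
            raise ConfigError(f"unknown aggregation_mode {self.aggregation_mode!r}")
        if self.missing_policy not in MISSING_POLICIES:
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")
        for domain, scale in self.trend_scale.items():
            if scale not in ("relative", "absolute"):
                raise ConfigError(f"trend_scale[{domain!r}] must be relative|absolute")

    def to_dict(self) -> dict:
        """Echo of every effective value, for provenance logging."""
        out = dataclasses.asdict(self)
        out["trend_windows"] = {k: list(v) for k, v in self.trend_windows.items()}
        return out


def read_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML config; unspecified keys take the documented defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> RunConfig:
    defaults = RunConfig()
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key == "domain_weights":
            merged = dict(defaults.domain_weights)
            merged.update({str(k): float(v) for k, v in value.items()})
            kwargs[key] = merged
        elif key == "reference_years":
            merged = dict(defaults.reference_years)
            merged.update(
                {str(k): (None if v is None else int(v)) for k, v in value.items()}
            )
            kwargs[key] = merged
        elif key == "trend_windows":
            merged = dict(defaults.trend_windows)
            merged.update({str(k): (int(v[0]), int(v[1])) for k, v in value.items()})
            kwargs[key] = merged
        elif key == "trend_scale":
            merged = dict(defaults.trend_scale)
            merged.update({str(k): str(v) for k, v in value.items()})
            kwargs[key] = merged
        elif key == "within_domain_weights":
            kwargs[key] = {str(k): float(v) for k, v in value.items()}
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def read_metric_csv(path: Union[str, Path]) -> MetricTable:
    """Read a long-format metrics CSV into a validated-shape MetricTable.

    Conditions and metric definitions are registered from the rows;
    directions default by domain.  Raises :class:`MetricsFormatError` naming
    missing columns or the line of an unparseable value.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise MetricsFormatError(f"{path}: missing required columns: {missing}")

    def parse_number(col: str, caster) -> pd.Series:
        try:
            return df[col].map(caster)
        except ValueError:
            for i, cell in enumerate(df[col]):
                try:
                    caster(cell)
                except ValueError:
                    # +2: header line plus 1-based indexing
                    raise MetricsFormatError(
                        f"{path}: line {i + 2}: unparseable {col} value {cell!r}"
                    ) from None
            raise  # pragma: no cover

    years = parse_number("year", int)
    values = parse_number("value", float)

    conditions: dict[str, Condition] = {}
    for cid, name in zip(df["condition_id"], df["condition_name"]):
        if cid not in conditions:
            conditions[cid] = Condition(condition_id=cid, name=name)

    definitions: dict[str, MetricDefinition] = {}
    for mid, domain, units in zip(df["metric_id"], df["domain"], df["units"]):
        if mid not in definitions:
            if domain not in DOMAINS:
                raise MetricsFormatError(
                    f"{path}: metric {mid!r} has unknown domain {domain!r}"
                )
            definitions[mid] = MetricDefinition(
                metric_id=mid,
                domain=domain,
                direction=default_direction(domain),
                units=units,
            )

    data = pd.DataFrame(
        {
            "condition_id": df["condition_id"],
            "metric_id": df["metric_id"],
            "year": years,
            "stratum": df["stratum"].replace("", None),
            "value": values,
        }
    )
    return MetricTable(conditions=conditions, definitions=definitions, data=data)


def write_metric_csv(table: MetricTable, path: Union[str, Path]) -> Path:
    """Write a MetricTable back to the canonical long-format CSV."""
    path = Path(path)
    df = table.data.copy()
    df["condition_name"] = df["condition_id"].map(
        {cid: c.name for cid, c in table.conditions.items()}
    )
    df["domain"] = df["metric_id"].map(
        {mid: d.domain for mid, d in table.definitions.items()}
    )
    df["units"] = df["metric_id"].map(
        {mid: d.units for mid, d in table.definitions.items()}
    )
    df["stratum"] = df["stratum"].fillna("")
    df = df.loc[:, list(CSV_COLUMNS)]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def write_results(
    results: list[GapResult],
    out_dir: Union[str, Path],
    decimals: int = 2,
    config: Optional[RunConfig] = None,
) -> dict[str, Path]:
    """Write the three result artifacts; return a manifest of paths.

    * ``scores.csv`` — one row per condition, domain and overall scores
      rounded to ``decimals`` for the human-readable report;
    * ``results.json`` — full-precision, machine-readable, deterministic
      (sorted keys, no timestamps);
    * ``multifactor.csv`` — condition, burden score, cost score, innovation
      tier: the axes of the multifactor classification plot.
    """
    if not results:
        raise ValueError("results must be nonempty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ordered = sorted(results, key=lambda r: r.rank)
    scores = pd.DataFrame(
        {
            "condition_id": [r.condition_id for r in ordered],
            "condition": [r.name for r in ordered],
            "rank": [r.rank for r in ordered],
            "burden_score": [round(r.domain_scores["burden"], decimals) for r in ordered],
            "cost_score": [round(r.domain_scores["cost"], decimals) for r in ordered],
            "innovation_score": [
                round(r.domain_scores["innovation"], decimals) for r in ordered
            ],
            "overall_gap": [round(r.overall_gap, decimals) for r in ordered],
            "overall_tier": [r.tiers.get("overall", "") for r in ordered],
            "opportunity": [r.opportunity_flag for r in ordered],
            "reason": [r.reason for r in ordered],
        }
    )
    scores_path = out_dir / "scores.csv"
    scores.to_csv(scores_path, index=False, encoding="utf-8")

    payload = {
        "config": config.to_dict() if config is not None else None,
        "results": [
            {
                "condition_id": r.condition_id,
                "name": r.name,
                "domain_scores": r.domain_scores,
                "overall_gap": r.overall_gap,
                "rank": r.rank,
                "tiers": r.tiers,
                "opportunity_flag": r.opportunity_flag,
                "reason": r.reason,
            }
            for r in ordered
        ],
    }
    json_path = out_dir / "results.json"
    json_path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    plot = pd.DataFrame(
        {
            "condition": [r.name for r in ordered],
            "burden_score": [r.domain_scores["burden"] for r in ordered],
            "cost_score": [r.domain_scores["cost"] for r in ordered],
            "innovation_tier": [r.tiers.get("innovation", "") for r in ordered],
        }
    )
    plot_path = out_dir / "multifactor.csv"
    plot.to_csv(plot_path, index=False, encoding="utf-8")

    return {"scores": scores_path, "json": json_path, "multifactor": plot_path}


def read_results_json(path: Union[str, Path]) -> list[GapResult]:
    """Load results.json back into GapResult records."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed results JSON: {exc}") from exc
    return [
        GapResult(
            condition_id=entry["condition_id"],
            name=entry["name"],
            domain_scores=entry["domain_scores"],
            overall_gap=entry["overall_gap"],
            rank=entry["rank"],
            tiers=entry.get("tiers", {}),
            opportunity_flag=entry.get("opportunity_flag", False),
            reason=entry.get("reason", ""),
        )
        for entry in payload["results"]
    ]
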