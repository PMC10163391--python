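"""Core domain types for condition-level gap scoring.

The framework scores each medical condition on three domains — public health
burden, health care cost, and biomedical product innovation — and integrates
them into an overall innovation-gap score.  These types are the shared
vocabulary of every stage: conditions, metric definitions, long-format
observations, and per-condition results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import pandas as pd

#: The three pilot domains.  The vocabulary is extensible through metric
#: definitions, but every built-in policy assumes this triple.
DOMAINS = ("burden", "cost", "innovation")

#: Direction flags: a ``gap_increasing`` criterion raises the gap score as its
#: value rises (burden, cost); a ``gap_decreasing`` criterion lowers it
#: (innovation activity).
GAP_INCREASING = "gap_increasing"
GAP_DECREASING = "gap_decreasing"
DIRECTIONS = (GAP_INCREASING, GAP_DECREASING)

METRIC_KINDS = ("cross_sectional", "trend", "disparity")

#: Canonical observation-table columns (long format).
OBSERVATION_COLUMNS = ("condition_id", "metric_id", "year", "stratum", "value")


def default_direction(domain: str) -> str:
    """Burden and cost metrics raise the gap; innovation activity lowers it."""
    return GAP_DECREASING if domain == "innovation" else GAP_INCREASING


@dataclass(frozen=True)
class Condition:
    """A medical disorder under study.

    ``icd10_codes`` is carried as opaque labels; no validation against an
    official code list is attempted.
    """

    condition_id: str
    name: str
    icd10_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.condition_id:
            raise ValueError("condition_id must be nonempty")
        if not self.name:
            raise ValueError(f"condition {self.condition_id!r}: name must be nonempty")


@dataclass(frozen=True)
class MetricDefinition:
    """One measurable quantity within a domain.

    ``direction`` defaults by domain: burden and cost metrics are
    gap-increasing (more is worse), innovation metrics gap-decreasing
    (more activity is better).
    """

    metric_id: str
    domain: str
    direction: Optional[str] = None
    units: str = ""
    kind: str = "cross_sectional"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(
                f"metric {self.metric_id!r}: unknown domain {self.domain!r}; "
                f"expected one of {DOMAINS}"
            )
        if self.kind not in METRIC_KINDS:
            raise ValueError(
                f"metric {self.metric_id!r}: unknown kind {self.kind!r}"
            )
        if self.direction is None:
            object.__setattr__(self, "direction", default_direction(self.domain))
        elif self.direction not in DIRECTIONS:
            raise ValueError(
                f"metric {self.metric_id!r}: unknown direction {self.direction!r}"
            )


@dataclass(frozen=True)
class MetricObservation:
    """One value of one metric for one condition in one year.

    ``stratum`` is None for unstratified observations; stratified rows (used
    by the disparity summary) carry labels like ``"sex:female"`` where the
    prefix names the stratification and the suffix the group.
    """

    condition_id: str
    metric_id: str
    year: int
    value: float
    stratum: Optional[str] = None


@dataclass
class MetricTable:
    """Long-format observation table with its condition and metric registries.

    Observations are held in a pandas DataFrame (columns
    ``condition_id, metric_id, year, stratum, value``) for vectorised
    processing; :attr:`observations` iterates them as records.
    """

    conditions: dict[str, Condition] = field(default_factory=dict)
    definitions: dict[str, MetricDefinition] = field(default_factory=dict)
    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(OBSERVATION_COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = [c for c in OBSERVATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation frame missing columns: {missing}")
        self.data = self.data.loc[:, list(OBSERVATION_COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_observations(
        cls,
        observations: list[MetricObservation],
        conditions: list[Condition],
        definitions: list[MetricDefinition],
    ) -> "MetricTable":
        frame = pd.DataFrame(
            [
                (o.condition_id, o.metric_id, int(o.year), o.stratum, float(o.value))
                for o in observations
            ],
            columns=list(OBSERVATION_COLUMNS),
        )
        return cls(
            conditions={c.condition_id: c for c in conditions},
            definitions={d.metric_id: d for d in definitions},
            data=frame,
        )

    @property
    def observations(self) -> Iterator[MetricObservation]:
        for row in self.data.itertuples(index=False):
            yield MetricObservation(
                condition_id=row.condition_id,
                metric_id=row.metric_id,
                year=int(row.year),
                stratum=None if pd.isna(row.stratum) or row.stratum == "" else row.stratum,
                value=float(row.value),
            )

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def metrics_in_domain(self, domain: str) -> list[MetricDefinition]:
        return [d for d in self.definitions.values() if d.domain == domain]


@dataclass(frozen=True)
class ValidationFinding:
    """A single invariant violation: which rule, and the offending record."""

    invariant: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.invariant}] {self.message}"


@dataclass
class GapResult:
    """Per-condition output of the full pipeline.

    ``domain_scores`` maps burden/cost/innovation to scores in [0, 1];
    ``tiers`` maps each domain plus ``"overall"`` to high/middle/low; rank 1
    is the largest overall gap.
    """

    condition_id: str
    name: str
    domain_scores: dict[str, float]
    overall_gap: float
    rank: int
    tiers: dict[str, str] = field(default_factory=dict)
    opportunity_flag: bool = False
    reason: str = ""


def validate_table(table: MetricTable) -> list[ValidationFinding]:
    """Check every table invariant; return findings rather than raising.

    An empty list means the table is well formed: nonnegative values, unique
    (condition, metric, year, stratum) keys, all references registered, and at
    least two conditions (scoring is relative).  Idempotent and side-effect
    free.
    """
    findings: list[ValidationFinding] = []
    df = table.data

    if table.n_conditions < 2:
        findings.append(
            ValidationFinding(
                "min_conditions",
                f"at least 2 conditions required for relative scoring, got "
                f"{table.n_conditions}",
            )
        )

    if len(df) == 0:
        return findings

    bad_value = df[(df["value"].isna()) | (df["value"] < 0)]
    for row in bad_value.itertuples(index=False):
        findings.append(
            ValidationFinding(
                "nonnegative_value",
                f"observation ({row.condition_id}, {row.metric_id}, {row.year}, "
                f"{row.stratum!r}) has value {row.value!r}; values must be >= 0",
            )
        )

    key_cols = ["condition_id", "metric_id", "year", "stratum"]
    dup_mask = df.duplicated(subset=key_cols, keep=False)
    if dup_mask.any():
        for key, _ in df[dup_mask].groupby(key_cols, dropna=False):
            findings.append(
                ValidationFinding(
                    "unique_key",
                    f"duplicated observation key (condition_id, metric_id, year, "
                    f"stratum) = {tuple(key)}",
                )
            )

    unknown_cond = sorted(set(df["condition_id"]) - set(table.conditions))
    for cid in unknown_cond:
        findings.append(
            ValidationFinding(
                "registered_condition",
                f"observation references unregistered condition {cid!r}",
            )
        )
    unknown_metric = sorted(set(df["metric_id"]) - set(table.definitions))
    for mid in unknown_metric:
        findings.append(
            ValidationFinding(
                "registered_metric",
                f"observation references unregistered metric {mid!r}",
            )
        )
    return findings
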