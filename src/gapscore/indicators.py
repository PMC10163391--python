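"""Derived metrics computed from raw observations.

Three families:

* the Healthy People 2020 **disparity summary rate ratio** — for a stratified
  rate (e.g. mortality by race/ethnicity), the mean rate of the non-reference
  groups divided by the most favorable group's rate, oriented to be >= 1 and
  maximised over stratifications (sex, age, race/ethnicity);
* **longitudinal trends** — absolute and relative change of a metric between
  two reference years;
* the **innovation deficit** — the complement ``1 - s`` of an innovation
  activity score, the form in which "least innovation" is usually reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional


class UndefinedRatioError(ValueError):
    """Raised when the most favorable group's rate is zero."""


@dataclass(frozen=True)
class StratifiedRates:
    """Group rates (per 100 000) for one outcome under one stratification.

    ``adverse=True`` means a lower rate is more favorable (mortality, YLD);
    ``adverse=False`` means a higher rate is more favorable (e.g. screening
    coverage).
    """

    outcome: str
    rates: Mapping[str, float]
    adverse: bool = True

    def __post_init__(self) -> None:
        if len(self.rates) < 2:
            raise ValueError(f"{self.outcome!r}: need >= 2 groups, got {len(self.rates)}")
        if any(r < 0 or math.isnan(r) for r in self.rates.values()):
            raise ValueError(f"{self.outcome!r}: rates must be nonnegative")
        if not any(r > 0 for r in self.rates.values()):
            raise ValueError(f"{self.outcome!r}: at least one rate must be positive")


@dataclass(frozen=True)
class TrendResult:
    """Change of a metric between two calendar years."""

    metric_id: str
    start_year: int
    end_year: int
    absolute_change: float
    relative_change: Optional[float]  # None when the start value is 0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError(
                f"{self.metric_id!r}: end_year {self.end_year} must exceed "
                f"start_year {self.start_year}"
            )


def disparity_ratio(strata: StratifiedRates) -> float:
    """Summary rate ratio: mean of the other groups over the best group.

    The most favorable group holds the minimum rate when the outcome is
    adverse, the maximum otherwise.  The ratio is oriented so that it is
    always >= 1 and equals 1 exactly when all group rates are equal.

    Raises
    ------
    UndefinedRatioError
        If the denominator (for adverse outcomes the most favorable rate, for
        favorable outcomes the mean of the non-reference groups) is zero.
    """
    values = list(strata.rates.values())
    if strata.adverse:
        best = min(values)
        others = sorted(values)[1:]  # drop one instance of the minimum
        mean_others = sum(others) / len(others)
        if best == 0:
            raise UndefinedRatioError(
                f"{strata.outcome!r}: most favorable group rate is 0; "
                "ratio undefined (consider a rate-difference fallback)"
            )
        return mean_others / best
    best = max(values)
    others = sorted(values)[:-1]
    mean_others = sum(others) / len(others)
    if mean_others == 0:
        raise UndefinedRatioError(
            f"{strata.outcome!r}: non-reference group mean rate is 0; ratio undefined"
        )
    return best / mean_others


def summary_disparity(
    per_stratification: Mapping[str, StratifiedRates],
) -> tuple[float, str]:
    """Maximum disparity ratio across stratifications, and which attains it.

    Ties are broken by stratification label (ascending) for determinism.
    """
    if not per_stratification:
        raise ValueError("need at least one stratification")
    ratios: dict[str, float] = {}
    for label, strata in sorted(per_stratification.items()):
        try:
            ratios[label] = disparity_ratio(strata)
        except UndefinedRatioError as exc:
            raise UndefinedRatioError(f"stratification {label!r}: {exc}") from exc
    best_label = max(sorted(ratios), key=lambda k: ratios[k])
    return ratios[best_label], best_label


def trend(
    series: Mapping[int, float], start_year: int, end_year: int, metric_id: str = ""
) -> TrendResult:
    """Absolute and relative change between two years of a series.

    ``relative_change`` preserves sign and is None when the start value is 0.
    """
    for year in (start_year, end_year):
        if year not in series:
            raise KeyError(f"metric {metric_id!r}: year {year} missing from series")
    start, end = series[start_year], series[end_year]
    absolute = end - start
    relative = absolute / start if start > 0 else None
    return TrendResult(
        metric_id=metric_id,
        start_year=start_year,
        end_year=end_year,
        absolute_change=absolute,
        relative_change=relative,
    )


def innovation_deficit(score: float) -> float:
    """Complement ``1 - score`` of an innovation activity score in [0, 1].

    A tabulated innovation score of 0.05 (very little activity) corresponds
    to a deficit of 0.95.  Involutive: ``deficit(deficit(s)) == s``.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"innovation score must lie in [0, 1], got {score}")
    return 1.0 - score
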