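"""TOPSIS: Technique for Order of Preference by Similarity to Ideal Solution.

Given an alternatives × criteria matrix of nonnegative values, per-criterion
direction flags and positive weights, the method

1. normalises each criterion column (vector or min-max normalisation),
2. applies the (sum-normalised) weights,
3. forms the ideal point A+ (best value on every criterion) and the
   anti-ideal point A- (worst value on every criterion),
4. measures each alternative's Euclidean separation from both points, and
5. returns the **gap score** ``G_i = d_i+ / (d_i+ + d_i-)`` — the relative
   closeness to the anti-ideal.

With ``gap_increasing`` criteria (burden, cost) the best value is the column
minimum; with ``gap_decreasing`` criteria (innovation activity) it is the
maximum.  G is 0 for an alternative sitting at the ideal point, 1 at the
anti-ideal point: high score = large unmet-need/innovation imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DIRECTIONS, GAP_INCREASING

NORMALIZATIONS = ("vector", "minmax")


class DegenerateColumnError(ValueError):
    """An all-zero criterion column cannot be vector-normalised."""


@dataclass
class DecisionMatrix:
    """Alternatives × criteria input to TOPSIS.

    values[i, j] is alternative i's raw value on criterion j (nonnegative);
    directions[j] says whether a high value raises the gap; weights are
    positive and are sum-normalised internally, so only their ratios matter.
    """

    alternatives: list[str]
    criteria: list[str]
    values: np.ndarray
    directions: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n, m = len(self.alternatives), len(self.criteria)
        if n < 2:
            raise ValueError("need at least 2 alternatives for relative ranking")
        if m < 1:
            raise ValueError("need at least 1 criterion")
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} != ({n} alternatives, {m} criteria)"
            )
        if len(self.directions) != m:
            raise ValueError("one direction flag per criterion required")
        for d in self.directions:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
        if self.weights.shape != (m,):
            raise ValueError("one weight per criterion required")
        if not np.all(self.weights > 0):
            raise ValueError("weights must be strictly positive")
        if np.any(np.isnan(self.values)) or np.any(self.values < 0):
            raise ValueError("matrix values must be nonnegative and finite")


@dataclass
class TopsisTrace:
    """Full intermediate state of one TOPSIS run, serialisable for provenance."""

    alternatives: list[str]
    criteria: list[str]
    normalized: np.ndarray
    weighted: np.ndarray
    ideal: np.ndarray
    anti_ideal: np.ndarray
    d_best: np.ndarray
    d_worst: np.ndarray
    gap: np.ndarray

    def to_dict(self) -> dict:
        return {
            "alternatives": list(self.alternatives),
            "criteria": list(self.criteria),
            "normalized": self.normalized.tolist(),
            "weighted": self.weighted.tolist(),
            "ideal": self.ideal.tolist(),
            "anti_ideal": self.anti_ideal.tolist(),
            "d_best": self.d_best.tolist(),
            "d_worst": self.d_worst.tolist(),
            "gap": self.gap.tolist(),
        }


def normalize(matrix: DecisionMatrix, method: str = "vector") -> np.ndarray:
    """Column-wise normalisation of the raw values.

    ``vector``: r_ij = x_ij / sqrt(sum_i x_ij^2) — the classic TOPSIS choice,
    invariant to rescaling a column (units drop out).  An all-zero column has
    no direction information and raises :class:`DegenerateColumnError`.

    ``minmax``: r_ij = (x_ij - min_i) / (max_i - min_i); a constant column
    maps to 0.5 by convention (no alternative is better or worse on it).
    """
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}; expected {NORMALIZATIONS}")
    x = matrix.values
    if method == "vector":
        norms = np.sqrt((x**2).sum(axis=0))
        zero = norms == 0
        if zero.any():
            bad = [matrix.criteria[j] for j in np.flatnonzero(zero)]
            raise DegenerateColumnError(
                f"all-zero criterion column(s) under vector normalization: {bad}"
            )
        return x / norms
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = hi - lo
    r = np.full_like(x, 0.5)
    ok = span > 0
    r[:, ok] = (x[:, ok] - lo[ok]) / span[ok]
    return r


def reference_points(
    weighted: np.ndarray, directions: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (A+) and anti-ideal (A-) points of the weighted matrix.

    On a gap-increasing criterion the ideal holds the column minimum (low
    burden/cost is best); on a gap-decreasing criterion the maximum (high
    innovation is best).  The anti-ideal is the componentwise opposite.
    """
    lo, hi = weighted.min(axis=0), weighted.max(axis=0)
    inc = np.array([d == GAP_INCREASING for d in directions])
    a_best = np.where(inc, lo, hi)
    a_worst = np.where(inc, hi, lo)
    return a_best, a_worst


def gap_scores(matrix: DecisionMatrix, normalization: str = "vector") -> TopsisTrace:
    """Run the full TOPSIS computation and return the trace.

    G_i = d_i+ / (d_i+ + d_i-) with Euclidean separations from the ideal and
    anti-ideal points.  If every alternative is identical (both separations
    zero) all scores are 0.5 by convention.
    """
    r = normalize(matrix, normalization)
    w = matrix.weights / matrix.weights.sum()
    v = r * w
    a_best, a_worst = reference_points(v, matrix.directions)
    d_best = np.sqrt(((v - a_best) ** 2).sum(axis=1))
    d_worst = np.sqrt(((v - a_worst) ** 2).sum(axis=1))
    denom = d_best + d_worst
    gap = np.full(len(matrix.alternatives), 0.5)
    ok = denom > 0
    gap[ok] = d_best[ok] / denom[ok]
    return TopsisTrace(
        alternatives=list(matrix.alternatives),
        criteria=list(matrix.criteria),
        normalized=r,
        weighted=v,
        ideal=a_best,
        anti_ideal=a_worst,
        d_best=d_best,
        d_worst=d_worst,
        gap=gap,
    )
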