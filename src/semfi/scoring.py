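"""Nonlinear indicator scoring and soil-fertility-index aggregation.

Each raw indicator value x is mapped to a unitless score in (0, 1) by the
sigmoid

    S(x) = 1 / (1 + (x / x0)^b)

where x0 is a reference level (by default the dataset mean of that
indicator, pooled over all samples so that scores stay comparable across
age groups and depth layers) and b is the slope: -2.5 for "more is better"
indicators (score increases with x, 0.5 exactly at the mean) and +2.5 for
"less is better" ones.  All six nutrient indicators default to more-is-
better.  The soil fertility index of a sample is the weighted sum
SFI = sum_i W_i S_i over the combined indicator weights, hence also in
(0, 1).  Scoring operates on raw measurement units, never on z-scores
(the ratio x/x0 requires a positive scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import IndicatorMismatchError, ScoringDomainError
from .io_tables import INDICATORS
from .weighting import WeightTable

MORE_IS_BETTER = "more_is_better"
LESS_IS_BETTER = "less_is_better"

#: Slope magnitude of the scoring sigmoid.
SLOPE_MAGNITUDE = 2.5


@dataclass
class ScoringConfig:
    """Direction and reference levels for indicator scoring.

    ``x0_values`` overrides the dataset-mean reference for the named
    indicators; otherwise the pooled mean of the scored table is used.
    """

    direction: dict[str, str] = field(
        default_factory=lambda: {ind: MORE_IS_BETTER for ind in INDICATORS}
    )
    x0_values: dict[str, float] = field(default_factory=dict)

    def slope(self, indicator: str) -> float:
        direction = self.direction.get(indicator, MORE_IS_BETTER)
        if direction == MORE_IS_BETTER:
            return -SLOPE_MAGNITUDE
        if direction == LESS_IS_BETTER:
            return SLOPE_MAGNITUDE
        raise ValueError(f"unknown direction {direction!r} for {indicator!r}")


def nonlinear_score(x, x0: float, b: float = -SLOPE_MAGNITUDE):
    """Sigmoid score S = 1 / (1 + (x/x0)^b), elementwise.

    S(x0) = 0.5 for any slope; with b < 0 the score rises with x (more is
    better), with b > 0 it falls.  x = 0 with b < 0 returns the limiting
    score 0.
    """
    if x0 <= 0:
        raise ScoringDomainError(f"reference level x0 must be positive, got {x0}")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ScoringDomainError("measured values must be non-negative")
    with np.errstate(divide="ignore"):
        ratio_pow = np.power(arr / x0, b)
    score = 1.0 / (1.0 + ratio_pow)
    score = np.where(np.isinf(ratio_pow), 0.0, score)
    if np.ndim(x) == 0:
        return float(score)
    return score


def score_indicators(
    table: pd.DataFrame,
    config: ScoringConfig | None = None,
    columns: Sequence[str] = INDICATORS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Score each indicator column of a raw-scale sample table.

    Returns the table with added ``s_<indicator>`` columns and the reference
    levels x0 actually used (dataset means unless overridden).
    """
    config = config or ScoringConfig()
    out = table.copy()
    x0_used: dict[str, float] = {}
    for col in columns:
        x0 = config.x0_values.get(col, float(np.mean(table[col].to_numpy(dtype=float))))
        if x0 <= 0:
            raise ScoringDomainError(f"reference level for {col!r} is {x0}; must be positive")
        x0_used[col] = x0
        out[f"s_{col}"] = nonlinear_score(table[col].to_numpy(dtype=float), x0, config.slope(col))
    return out, x0_used


def compute_sfi(
    scored: pd.DataFrame,
    weights: WeightTable | Mapping[str, float],
) -> pd.DataFrame:
    """Aggregate indicator scores into the soil fertility index.

    ``scored`` must carry ``s_<indicator>`` columns for exactly the
    indicators the weights cover; the combined weights must sum to 1.
    Adds an ``sfi`` column.
    """
    w = weights.combined_weights if isinstance(weights, WeightTable) else dict(weights)
    score_cols = {c[2:] for c in scored.columns if c.startswith("s_")}
    if score_cols != set(w):
        missing = sorted(set(w) - score_cols)
        extra = sorted(score_cols - set(w))
        raise IndicatorMismatchError(
            f"weights and scores cover different indicators (missing scores: {missing}, "
            f"unweighted scores: {extra})"
        )
    total = sum(w.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"combined weights must sum to 1, got {total}")
    out = scored.copy()
    sfi = np.zeros(len(out))
    for ind, weight in w.items():
        sfi += weight * out[f"s_{ind}"].to_numpy(dtype=float)
    out["sfi"] = sfi
    return out


def score_table(
    table: pd.DataFrame,
    weights: WeightTable | Mapping[str, float],
    config: ScoringConfig | None = None,
    columns: Sequence[str] = INDICATORS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Score raw indicators and aggregate the SFI in one step."""
    scored, x0_used = score_indicators(table, config=config, columns=columns)
    return compute_sfi(scored, weights), x0_used


def summarize_sfi(
    scored: pd.DataFrame,
    by: Sequence[str] = ("age_group", "depth_layer"),
) -> pd.DataFrame:
    """Mean, SD and count of the SFI per grouping cell.

    Row order is deterministic: the categorical order of the grouping keys
    (age group I-V, then depth shallow to deep).  Empty cells appear with
    n = 0 and missing mean/SD.
    """
    by = list(by)
    for key in by:
        if key not in scored.columns:
            raise KeyError(f"grouping key {key!r} not in table")
    grouped = scored.groupby(by, observed=False, sort=True)["sfi"]
    summary = grouped.agg(n="count", mean_sfi="mean", sd_sfi=lambda s: s.std(ddof=1))
    summary = summary.reset_index()
    summary.loc[summary["n"] == 0, ["mean_sfi", "sd_sfi"]] = np.nan
    summary["n"] = summary["n"].astype(int)
    return summary
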