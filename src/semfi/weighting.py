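"""Hierarchical indicator weights from standardized path coefficients.

The fitted structural model yields one standardized path per nutrient group
(second-order factor -> group, gamma) and one standardized loading per
indicator (group -> indicator, lambda).  Weights follow by two-level
proportional normalization:

    beta_h = gamma_h / sum_h' gamma_h'          (group weights)
    rho_k  = lambda_k / sum_{k' in group} lambda_k'   (within-group weights)
    W_k    = beta_{h(k)} * rho_k                (combined weights)

so that group weights, within-group weights and combined weights each sum
to 1.  The combined weights are what the fertility-index aggregation
consumes.  Negative or zero coefficients are rejected: proportional shares
of mixed-sign paths have no meaningful interpretation and call for a model
review instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cfa import CfaFit


@dataclass
class WeightTable:
    """Two-level weight structure over indicator groups."""

    group_weights: dict[str, float]
    indicator_weights: dict[str, float]
    combined_weights: dict[str, float]
    groups: dict[str, tuple[str, ...]]
    target: str = "SoilFertility"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, inds in self.groups.items():
            for ind in inds:
                rows.append(
                    (
                        self.target,
                        group,
                        self.group_weights[group],
                        ind,
                        self.indicator_weights[ind],
                        self.combined_weights[ind],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "target_layer",
                "group",
                "group_weight",
                "indicator",
                "indicator_weight",
                "combined_weight",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "WeightTable":
        groups: dict[str, list[str]] = {}
        gw, iw, cw = {}, {}, {}
        for _, row in frame.iterrows():
            groups.setdefault(row["group"], []).append(row["indicator"])
            gw[row["group"]] = float(row["group_weight"])
            iw[row["indicator"]] = float(row["indicator_weight"])
            cw[row["indicator"]] = float(row["combined_weight"])
        return cls(
            group_weights=gw,
            indicator_weights=iw,
            combined_weights=cw,
            groups={g: tuple(v) for g, v in groups.items()},
            target=str(frame["target_layer"].iloc[0]),
        )


def compute_weights(
    gamma: Mapping[str, float],
    loadings: Mapping[str, Mapping[str, float]],
    target: str = "SoilFertility",
) -> WeightTable:
    """Normalize standardized path coefficients into a weight table.

    Parameters
    ----------
    gamma
        Group name -> standardized second-order path coefficient.
    loadings
        Group name -> {indicator -> standardized loading}; keys must match
        ``gamma``.
    """
    if set(gamma) != set(loadings):
        raise ValueError("gamma and loadings must cover the same groups")
    for h, g in gamma.items():
        if not g > 0:
            raise ValueError(
                f"group path for {h!r} is {g}; all coefficients must be positive — "
                "review path signs before weighting"
            )
        for k, lam in loadings[h].items():
            if not lam > 0:
                raise ValueError(
                    f"loading for {k!r} is {lam}; all coefficients must be positive — "
                    "review path signs before weighting"
                )
    gamma_total = sum(gamma.values())
    group_weights = {h: g / gamma_total for h, g in gamma.items()}
    indicator_weights: dict[str, float] = {}
    combined: dict[str, float] = {}
    for h, lams in loadings.items():
        lam_total = sum(lams.values())
        for k, lam in lams.items():
            rho = lam / lam_total
            indicator_weights[k] = rho
            combined[k] = group_weights[h] * rho
    return WeightTable(
        group_weights=group_weights,
        indicator_weights=indicator_weights,
        combined_weights=combined,
        groups={h: tuple(lams) for h, lams in loadings.items()},
        target=target,
    )


def weights_from_fit(fit: CfaFit) -> WeightTable:
    """Build the weight table from a converged second-order CFA fit."""
    if not fit.std_gamma:
        raise ValueError("fit has no second-order paths; weights need gamma coefficients")
    loadings = {
        fac: {ind: fit.std_loadings[(ind, fac)] for ind in inds}
        for fac, inds in fit.spec.first_order_factors.items()
    }
    return compute_weights(
        fit.std_gamma, loadings, target=fit.spec.second_order_factor or "SoilFertility"
    )
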