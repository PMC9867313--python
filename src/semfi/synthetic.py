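"""Synthetic soil-nutrient datasets with a known latent factor structure.

The generator emulates the sampling design behind the fertility-index
pipeline: 5 stand age groups x 5 replicate plots x 5 sampling points x 4
depth layers = 500 cores, each measured on six nutrient indicators.  Data
are drawn from the correlated two-factor measurement model the pipeline is
built to recover: two unit-variance latent factors (total and available
nutrients) with a fixed correlation; each standardized indicator is
lambda * factor + sqrt(1 - lambda^2) * noise.  Standardized draws are then
mapped onto realistic measurement scales per design cell — an age-group
mean and SD per indicator, with a depth-decline multiplier profile across
layers (steeper for SOM/TN/AN than for TP/AP/AK, mirroring the stronger
depth stratification of organic matter and nitrogen).  Depth multipliers
are renormalized to mean 1 within each indicator so that per-age-group
means pooled over depths hit their calibration targets.

Negative draws are resampled (not clipped, which would pile mass at 0);
available phosphorus, whose realistic SD rivals its mean, instead uses a
mean-preserving lognormal transform of its standardized draw so values stay
positive.

``SyntheticSpec.homogeneous()`` switches off all cell effects (one global
mean/SD per indicator), giving i.i.d. draws from the pure factor model —
the configuration for parameter-recovery experiments, since age/depth mean
gradients add between-cell covariance on top of the factor structure when
cells are pooled.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import AGE_GROUPS, DEPTH_LAYERS, INDICATORS, _as_categorical

#: Default standardized loadings of the two-factor measurement model
#: (som, tn, tp on total nutrients; an, ap, ak on available nutrients).
DEFAULT_LOADINGS: dict[str, float] = {
    "som": 0.89,
    "tn": 0.96,
    "tp": 0.46,
    "an": 0.42,
    "ap": 0.78,
    "ak": 0.77,
}

#: Default correlation between the two nutrient factors (0.51 * 0.60, the
#: product of the second-order paths it is equivalent to).
DEFAULT_FACTOR_CORRELATION = 0.306

_FACTOR_OF = {"som": 0, "tn": 0, "tp": 0, "an": 1, "ap": 1, "ak": 1}

#: Per-age-group (mean, sd) calibration targets for each indicator, pooled
#: over depth layers.  SOM/TN/TP in g/kg, AN/AP/AK in mg/kg.
AGE_GROUP_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "I": {"som": (14.29, 0.37), "tn": (0.81, 0.08), "tp": (0.19, 0.07),
          "an": (60.98, 6.26), "ap": (3.68, 2.78), "ak": (40.16, 14.11)},
    "II": {"som": (13.07, 0.15), "tn": (0.74, 0.05), "tp": (0.17, 0.05),
           "an": (57.44, 11.83), "ap": (2.78, 1.90), "ak": (44.26, 12.57)},
    "III": {"som": (15.15, 0.41), "tn": (0.82, 0.05), "tp": (0.19, 0.07),
            "an": (61.71, 12.48), "ap": (2.60, 1.50), "ak": (46.87, 13.17)},
    "IV": {"som": (16.45, 0.27), "tn": (0.89, 0.09), "tp": (0.18, 0.05),
           "an": (65.20, 11.76), "ap": (5.31, 6.82), "ak": (49.97, 14.87)},
    "V": {"som": (18.15, 0.58), "tn": (0.86, 0.03), "tp": (0.20, 0.05),
          "an": (70.90, 10.75), "ap": (5.01, 7.78), "ak": (54.19, 10.94)},
}

#: Raw depth-decline multipliers across the four layers (shallow -> deep);
#: renormalized to mean 1 per indicator before use.
DEPTH_MULTIPLIERS: dict[str, tuple[float, float, float, float]] = {
    "som": (1.00, 0.90, 0.72, 0.55),
    "tn": (1.00, 0.90, 0.72, 0.55),
    "an": (1.00, 0.90, 0.72, 0.55),
    "tp": (1.00, 1.00, 0.90, 0.85),
    "ap": (1.00, 1.00, 0.90, 0.85),
    "ak": (1.00, 1.00, 0.90, 0.85),
}

#: Indicators whose noise is mapped through a lognormal transform.
LOGNORMAL_INDICATORS: frozenset[str] = frozenset({"ap"})

_MAX_RESAMPLE_ROUNDS = 200


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration; defaults reproduce the full 500-core design."""

    n_per_cell: int = 1
    loadings: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    factor_correlation: float = DEFAULT_FACTOR_CORRELATION
    cell_effects: Mapping[str, Mapping[str, tuple[float, float]]] | None = field(
        default_factory=lambda: {g: dict(v) for g, v in AGE_GROUP_MOMENTS.items()}
    )
    depth_multipliers: Mapping[str, tuple[float, ...]] | None = field(
        default_factory=lambda: dict(DEPTH_MULTIPLIERS)
    )
    lognormal_indicators: frozenset[str] = LOGNORMAL_INDICATORS
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for ind in INDICATORS:
            if ind not in self.loadings:
                raise ValueError(f"loading missing for indicator {ind!r}")
            if abs(self.loadings[ind]) > 1:
                raise ValueError(f"|loading| for {ind!r} exceeds 1")
        if abs(self.factor_correlation) > 1:
            raise ValueError("|factor correlation| must be <= 1")
        if self.cell_effects is not None:
            for group, moments in self.cell_effects.items():
                for ind, (_, sd) in moments.items():
                    if sd <= 0:
                        raise ValueError(f"target SD for {group}/{ind} must be > 0")
        # implied indicator correlation matrix must be positive definite
        eigvals = np.linalg.eigvalsh(self.implied_correlation())
        if eigvals.min() <= 1e-12:
            raise ValueError("implied indicator correlation matrix is not positive definite")

    @classmethod
    def homogeneous(cls, mean: float = 50.0, sd: float = 5.0, **kwargs) -> "SyntheticSpec":
        """Pure factor-model draws: one global (mean, sd) for every cell."""
        moments = {g: {ind: (mean, sd) for ind in INDICATORS} for g in AGE_GROUPS}
        return cls(
            cell_effects=moments,
            depth_multipliers=None,
            lognormal_indicators=frozenset(),
            **kwargs,
        )

    def implied_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix of the standardized indicators."""
        lam = np.array([self.loadings[ind] for ind in INDICATORS])
        phi = np.array(
            [
                [1.0 if _FACTOR_OF[a] == _FACTOR_OF[b] else self.factor_correlation
                 for b in INDICATORS]
                for a in INDICATORS
            ]
        )
        sigma = np.outer(lam, lam) * phi
        np.fill_diagonal(sigma, 1.0)
        return sigma

    def to_dict(self) -> dict:
        return {
            "n_per_cell": self.n_per_cell,
            "loadings": dict(self.loadings),
            "factor_correlation": self.factor_correlation,
            "cell_effects": None
            if self.cell_effects is None
            else {g: {i: list(v) for i, v in m.items()} for g, m in self.cell_effects.items()},
            "depth_multipliers": None
            if self.depth_multipliers is None
            else {i: list(v) for i, v in self.depth_multipliers.items()},
            "lognormal_indicators": sorted(self.lognormal_indicators),
            "seed": self.seed,
        }


def _normalized_depth_multipliers(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    out = {}
    for ind in INDICATORS:
        if spec.depth_multipliers is None or ind not in spec.depth_multipliers:
            out[ind] = np.ones(len(DEPTH_LAYERS))
        else:
            m = np.asarray(spec.depth_multipliers[ind], dtype=float)
            out[ind] = m / m.mean()
    return out


def _standardized_draws(
    spec: SyntheticSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draws from the two-factor model, unit variance per indicator.

    Returns the n x 6 standardized values z = lam*f + sqrt(1-lam^2)*e and the
    n x 2 factor draws (needed to resample noise without touching the latent
    structure).
    """
    phi = spec.factor_correlation
    f1 = rng.standard_normal(n)
    f2 = phi * f1 + np.sqrt(1.0 - phi * phi) * rng.standard_normal(n)
    factors = np.column_stack([f1, f2])
    z = np.empty((n, len(INDICATORS)))
    for j, ind in enumerate(INDICATORS):
        lam = spec.loadings[ind]
        z[:, j] = lam * factors[:, _FACTOR_OF[ind]] + np.sqrt(1.0 - lam * lam) * (
            rng.standard_normal(n)
        )
    return z, factors


def generate(spec: SyntheticSpec | None = None) -> pd.DataFrame:
    """Generate a soil-sample table; deterministic given ``spec.seed``."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    cells = list(
        itertools.product(
            AGE_GROUPS,
            range(1, 6),
            range(1, 6),
            range(len(DEPTH_LAYERS)),
            range(spec.n_per_cell),
        )
    )
    n = len(cells)
    z, factors = _standardized_draws(spec, n, rng)
    depth_mult = _normalized_depth_multipliers(spec)

    records = []
    values = np.empty((n, len(INDICATORS)))
    for row, (age, plot, point, d_idx, rep) in enumerate(cells):
        suffix = f"-r{rep + 1}" if spec.n_per_cell > 1 else ""
        records.append(
            {
                "sample_id": f"{age}-p{plot}-s{point}-d{d_idx + 1}{suffix}",
                "age_group": age,
                "plot": plot,
                "point": point,
                "depth_layer": DEPTH_LAYERS[d_idx],
            }
        )
        for j, ind in enumerate(INDICATORS):
            if spec.cell_effects is None:
                values[row, j] = z[row, j]
                continue
            mu_age, sd = spec.cell_effects[age][ind]
            mu = mu_age * depth_mult[ind][d_idx]
            if ind in spec.lognormal_indicators:
                cv = sd / mu
                s = np.sqrt(np.log1p(cv * cv))
                values[row, j] = mu * np.exp(s * z[row, j] - 0.5 * s * s)
            else:
                values[row, j] = mu + sd * z[row, j]

    if spec.cell_effects is not None:
        _resample_negatives(spec, values, z, factors, cells, depth_mult, rng)

    table = pd.DataFrame.from_records(records)
    for j, ind in enumerate(INDICATORS):
        table[ind] = values[:, j]
    return _as_categorical(table)


def _resample_negatives(spec, values, z, factors, cells, depth_mult, rng):
    """Redraw the idiosyncratic noise of any negative cell value.

    The latent factor contribution is kept; only the indicator's unique
    noise e in z = lam*f + sqrt(1-lam^2)*e is redrawn, so the factor
    structure is preserved up to the slight truncation of the noise
    distribution.  After the round limit any stragglers are clipped at 0.
    """
    for j, ind in enumerate(INDICATORS):
        if ind in spec.lognormal_indicators:
            continue  # lognormal values are positive by construction
        lam = spec.loadings[ind]
        noise_sd = np.sqrt(1.0 - lam * lam)
        latent = lam * factors[:, _FACTOR_OF[ind]]
        for _ in range(_MAX_RESAMPLE_ROUNDS):
            bad = np.nonzero(values[:, j] < 0)[0]
            if bad.size == 0:
                break
            for row in bad:
                age, _, _, d_idx, _ = cells[row]
                mu_age, sd = spec.cell_effects[age][ind]
                mu = mu_age * depth_mult[ind][d_idx]
                z[row, j] = latent[row] + noise_sd * rng.standard_normal()
                values[row, j] = mu + sd * z[row, j]
        else:
            values[:, j] = np.clip(values[:, j], 0.0, None)


def write_truth(spec: SyntheticSpec, path) -> None:
    """Record the generating parameters next to a generated dataset."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(spec.to_dict(), handle, indent=2, sort_keys=True)


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Copy of ``spec`` with a different random seed."""
    return replace(spec, seed=seed)
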