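"""Pre-model adequacy screening for factor-analytic data.

Before a covariance-structure model is entertained, the indicator battery is
screened for internal consistency (Cronbach's alpha), sampling adequacy
(Kaiser-Meyer-Olkin measure) and non-sphericity (Bartlett's chi-square
test).  All three operate on the indicator correlation structure, so KMO and
Bartlett are invariant to affine rescaling of individual indicators; alpha
is computed on the (z-scored) matrix handed to it and is invariant to
additive shifts only.

Verdict bands
-------------
alpha        > 0.8 high; 0.5-0.8 acceptable; < 0.5 not acceptable
KMO          > 0.7 suitable for factor analysis; > 0.5 acceptable
Bartlett     p < 0.05 rejects sphericity (correlations present)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateColumnError, SingularMatrixError


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha for an n x k item matrix.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total)), sample
    variances with denominator n-1.
    """
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    if n < 3:
        raise ValueError("alpha requires at least 3 observations")
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateColumnError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def _correlation(matrix) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateColumnError("constant column; correlation undefined")
    return np.corrcoef(x, rowvar=False)


def kmo_from_corr(corr) -> tuple[float, np.ndarray]:
    """KMO sampling adequacy from a correlation matrix.

    The anti-image partial correlations q_ij are taken from the inverse
    correlation matrix scaled by its diagonal; overall KMO is
    sum r^2 / (sum r^2 + sum q^2) over off-diagonal pairs, and the
    per-variable values use the same ratio restricted to one row.
    """
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "correlation matrix is singular; remove redundant variables"
        ) from exc
    d = np.sqrt(np.diag(rinv))
    partial = -rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = r[off] ** 2
    q2 = partial[off] ** 2
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    per_variable = np.array(
        [
            (r[i, off[i]] ** 2).sum() / ((r[i, off[i]] ** 2).sum() + (partial[i, off[i]] ** 2).sum())
            for i in range(p)
        ]
    )
    return overall, per_variable


def kmo(matrix) -> tuple[float, np.ndarray]:
    """KMO measure for an n x p indicator matrix; see :func:`kmo_from_corr`."""
    return kmo_from_corr(_correlation(matrix))


def bartlett_from_corr(corr, n: int) -> tuple[float, int, float]:
    """Bartlett's sphericity test from a correlation matrix and sample size.

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R|, df = p(p-1)/2; the p-value is the
    chi-square upper tail.
    """
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    if n <= p:
        raise ValueError("Bartlett's test requires n > p")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise SingularMatrixError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    chi2 = float(max(chi2, 0.0))
    df = p * (p - 1) // 2
    p_value = float(sps.chi2.sf(chi2, df))
    return chi2, df, p_value


def bartlett_sphericity(matrix) -> tuple[float, int, float]:
    """Bartlett's sphericity test for an n x p indicator matrix."""
    x = np.asarray(matrix, dtype=float)
    return bartlett_from_corr(_correlation(x), x.shape[0])


def _alpha_verdict(alpha: float) -> str:
    if alpha > 0.8:
        return "pass"
    if alpha > 0.5:
        return "acceptable"
    return "fail"


def _kmo_verdict(value: float) -> str:
    if value > 0.7:
        return "pass"
    if value > 0.5:
        return "acceptable"
    return "fail"


@dataclass
class ReliabilityReport:
    """Joint screening report over one indicator battery."""

    cronbach_alpha: float
    kmo_overall: float
    kmo_per_variable: dict[str, float]
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    verdicts: dict[str, str] = field(default_factory=dict)
    group_alphas: dict[str, float] = field(default_factory=dict)

    @property
    def adequate(self) -> bool:
        """True when every criterion is at least 'acceptable'."""
        return all(v in ("pass", "acceptable") for v in self.verdicts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cronbach_alpha", self.cronbach_alpha, ">0.8 high; 0.5-0.8 acceptable",
             self.verdicts["cronbach_alpha"]),
            ("kmo_overall", self.kmo_overall, ">0.7 suitable; >0.5 acceptable",
             self.verdicts["kmo_overall"]),
            ("bartlett_chi2", self.bartlett_chi2, "", ""),
            ("bartlett_df", self.bartlett_df, "", ""),
            ("bartlett_p", self.bartlett_p, "<0.05", self.verdicts["bartlett_p"]),
        ]
        for name, value in self.kmo_per_variable.items():
            rows.append((f"kmo[{name}]", value, "", ""))
        for name, value in self.group_alphas.items():
            rows.append((f"alpha[{name}]", value, "", ""))
        return pd.DataFrame(rows, columns=["criterion", "value", "reference", "verdict"])

    def describe(self) -> str:
        lines = [
            "Adequacy screening",
            f"  Cronbach's alpha : {self.cronbach_alpha:.4f} ({self.verdicts['cronbach_alpha']})",
            f"  KMO (overall)    : {self.kmo_overall:.4f} ({self.verdicts['kmo_overall']})",
            f"  Bartlett chi2    : {self.bartlett_chi2:.2f} on {self.bartlett_df} df, "
            f"p = {self.bartlett_p:.3g} ({self.verdicts['bartlett_p']})",
        ]
        return "\n".join(lines)


def screen(
    matrix,
    columns: list[str] | None = None,
    groups: dict[str, list[str]] | None = None,
) -> ReliabilityReport:
    """Run the full adequacy screen on an indicator matrix or DataFrame.

    Parameters
    ----------
    matrix
        n x p array or DataFrame of indicator values (typically z-scored).
    columns
        Names for the p columns (taken from the DataFrame if omitted).
    groups
        Optional indicator grouping; a per-group Cronbach alpha is reported
        alongside the joint all-indicator alpha.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = list(matrix.columns) if columns is None else list(columns)
        data = matrix[columns].to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        if columns is None:
            columns = [f"x{i + 1}" for i in range(data.shape[1])]
    alpha = cronbach_alpha(data)
    overall, per_var = kmo(data)
    chi2, df, p_value = bartlett_sphericity(data)
    group_alphas = {}
    for name, cols in (groups or {}).items():
        idx = [columns.index(c) for c in cols]
        group_alphas[name] = cronbach_alpha(data[:, idx])
    return ReliabilityReport(
        cronbach_alpha=alpha,
        kmo_overall=overall,
        kmo_per_variable=dict(zip(columns, per_var.tolist())),
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=p_value,
        verdicts={
            "cronbach_alpha": _alpha_verdict(alpha),
            "kmo_overall": _kmo_verdict(overall),
            "bartlett_p": "pass" if p_value < 0.05 else "fail",
        },
        group_alphas=group_alphas,
    )
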