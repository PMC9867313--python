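"""Model-fit battery and construct statistics for covariance-structure fits.

Absolute and incremental fit is judged against an independence baseline (all
indicators uncorrelated), whose ML chi-square is -(n-1) ln|R|.  Construct
quality is summarized by composite reliability CR = (sum lambda)^2 /
((sum lambda)^2 + sum(1 - lambda^2)) and average variance extracted
AVE = sum(lambda^2)/k over the standardized loadings, here computed over all
indicators as one composite.

Reference bands (verdict "fit" / "no-fit"):
chi2/df in [1, 3]; CFI, TLI, IFI > 0.90; SRMR < 0.08; CR > 0.7; AVE > 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cfa import CfaFit
from .exceptions import SingularMatrixError

REFERENCE_BANDS = {
    "cmin_df": "1-3",
    "cfi": ">0.90",
    "tli": ">0.90",
    "ifi": ">0.90",
    "srmr": "<0.08",
    "cr": ">0.7",
    "ave": ">0.5",
}


def _cov2corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise ValueError("covariance matrix has non-positive diagonal")
    return cov / np.outer(d, d)


def baseline_chi2(sample_cov, n: int) -> tuple[float, int]:
    """Chi-square and df of the independence (diagonal) baseline model.

    The ML discrepancy of the diagonal model against S reduces to -ln|R|,
    so chi2_B = -(n-1) ln|R| on p(p-1)/2 df.
    """
    S = np.asarray(sample_cov, dtype=float)
    R = _cov2corr(S)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise SingularMatrixError("sample covariance is singular")
    p = S.shape[0]
    return float(-(n - 1) * logdet), p * (p - 1) // 2


def comparative_indices(
    chi2_m: float, df_m: int, chi2_b: float, df_b: int
) -> tuple[float, float, float]:
    """CFI, TLI (NNFI) and IFI of a model against the independence baseline.

    CFI = 1 - max(chi2_M - df_M, 0) / max(chi2_B - df_B, chi2_M - df_M, 0),
    TLI = (chi2_B/df_B - chi2_M/df_M) / (chi2_B/df_B - 1),
    IFI = (chi2_B - chi2_M) / (chi2_B - df_M).

    TLI is undefined for a saturated model (df_M = 0) and returned as NaN.
    """
    if df_b <= 0:
        raise ValueError("baseline df must be positive")
    if chi2_m < 0 or chi2_b < 0 or df_m < 0:
        raise ValueError("chi-square values and df must be non-negative")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    cfi = min(max(cfi, 0.0), 1.0)
    if df_m == 0:
        tli = math.nan
    else:
        rb = chi2_b / df_b
        tli = (rb - chi2_m / df_m) / (rb - 1.0)
    ifi = (chi2_b - chi2_m) / (chi2_b - df_m)
    return float(cfi), float(tli), float(ifi)


def srmr(sample_cov, sigma_hat, include_diagonal: bool = True) -> float:
    """Standardized root mean square residual between sample and implied
    correlations, averaged over the p(p+1)/2 unique elements (or p(p-1)/2
    with ``include_diagonal=False``; correlation diagonals contribute 0)."""
    S = np.asarray(sample_cov, dtype=float)
    H = np.asarray(sigma_hat, dtype=float)
    if S.shape != H.shape:
        raise ValueError("sample and implied matrices must have the same shape")
    diff = _cov2corr(S) - _cov2corr(H)
    p = S.shape[0]
    iu = np.triu_indices(p, k=0 if include_diagonal else 1)
    n_el = p * (p + 1) // 2 if include_diagonal else p * (p - 1) // 2
    return float(np.sqrt(np.sum(diff[iu] ** 2) / n_el))


def composite_reliability(std_loadings) -> float:
    """CR = (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2))."""
    lam = np.asarray(list(std_loadings), dtype=float)
    if lam.size == 0:
        raise ValueError("at least one loading is required")
    if np.any(np.abs(lam) > 1 + 1e-9):
        raise ValueError("standardized loadings must lie in [-1, 1]")
    s = lam.sum() ** 2
    e = np.sum(1.0 - lam**2)
    if s + e == 0:
        return 0.0
    return float(s / (s + e))


def average_variance_extracted(std_loadings) -> float:
    """AVE = mean of squared standardized loadings."""
    lam = np.asarray(list(std_loadings), dtype=float)
    if lam.size == 0:
        raise ValueError("at least one loading is required")
    if np.any(np.abs(lam) > 1 + 1e-9):
        raise ValueError("standardized loadings must lie in [-1, 1]")
    return float(np.mean(lam**2))


def verdicts(
    cmin_df: float,
    cfi: float,
    tli: float,
    ifi: float,
    srmr_value: float,
    cr: float | None = None,
    ave: float | None = None,
) -> dict[str, str]:
    """Judge each statistic against its reference band."""
    out = {
        "cmin_df": "fit" if 1.0 <= cmin_df <= 3.0 else "no-fit",
        "cfi": "fit" if cfi > 0.90 else "no-fit",
        "tli": "n/a" if math.isnan(tli) else ("fit" if tli > 0.90 else "no-fit"),
        "ifi": "fit" if ifi > 0.90 else "no-fit",
        "srmr": "fit" if srmr_value < 0.08 else "no-fit",
    }
    if cr is not None:
        out["cr"] = "fit" if cr > 0.7 else "no-fit"
    if ave is not None:
        out["ave"] = "fit" if ave > 0.5 else "no-fit"
    return out


@dataclass
class FitIndexReport:
    """Fit battery plus construct statistics for one fitted model."""

    cmin_df: float
    cfi: float
    tli: float
    ifi: float
    srmr: float
    cr: float
    ave: float
    verdicts: dict[str, str]

    @property
    def all_fit(self) -> bool:
        return all(v in ("fit", "n/a") for v in self.verdicts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in ("cmin_df", "cfi", "tli", "ifi", "srmr", "cr", "ave"):
            rows.append(
                (key.upper() if key != "cmin_df" else "CMIN/DF",
                 getattr(self, key), REFERENCE_BANDS[key], self.verdicts.get(key, ""))
            )
        return pd.DataFrame(rows, columns=["index", "value", "reference_band", "verdict"])


def fit_index_report(fit: CfaFit, include_diagonal: bool = True) -> FitIndexReport:
    """Compute the full report for a converged CFA fit."""
    chi2_b, df_b = baseline_chi2(fit.sample_cov, fit.n)
    cfi, tli, ifi = comparative_indices(fit.chi2, fit.df, chi2_b, df_b)
    srmr_value = srmr(fit.sample_cov, fit.sigma_hat, include_diagonal=include_diagonal)
    lam = fit.std_loading_list()
    cr = composite_reliability(lam)
    ave = average_variance_extracted(lam)
    return FitIndexReport(
        cmin_df=fit.cmin_df,
        cfi=cfi,
        tli=tli,
        ifi=ifi,
        srmr=srmr_value,
        cr=cr,
        ave=ave,
        verdicts=verdicts(fit.cmin_df, cfi, tli, ifi, srmr_value, cr, ave),
    )
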