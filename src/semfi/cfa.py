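"""Confirmatory factor / second-order structural models fit by maximum likelihood.

The model family: observed indicators x load on first-order latent factors
(x = Lambda eta + delta); the first-order factors are either driven by one
second-order factor (eta_h = gamma_h xi + zeta_h) or simply correlated.  All
latent variables are identified by fixing their variances to 1, so the
estimated loadings and gamma paths are already on the standardized latent
scale and the fully standardized solution follows by rescaling each observed
variable by its implied standard deviation.

The implied covariance is Sigma(theta) = Lambda Phi Lambda' + Theta, where
Phi is the factor correlation matrix (built from gamma paths or estimated
directly) and Theta holds error variances plus any freed error covariances.
Estimation minimizes the ML discrepancy

    F(theta) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

with analytic gradients under L-BFGS-B; (n-1) * F_min is the model
chi-square on p(p+1)/2 - q degrees of freedom.  Because the free-loading /
free-error-variance family is invariant to separate rescaling of each
indicator, the fit is carried out internally on the sample correlation
matrix (better conditioned for raw soil units that differ by orders of
magnitude) and unstandardized estimates are mapped back to the input scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import NotConvergedError, SingularMatrixError
from .io_tables import INDICATORS

#: Lower bound at which Heywood (negative) error variances are clamped.
ERROR_VARIANCE_FLOOR = 1e-6

#: Gradient-norm threshold accepted as a stationary point.
GRAD_TOL = 1e-6

_IDENTIFICATIONS = ("equal_gamma", "free_gamma", "correlated")


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"error covariance requires two distinct indicators, got {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CfaModelSpec:
    """Latent structure: factors, indicator pattern, extra free parameters.

    Parameters
    ----------
    observed
        Ordered indicator names.
    first_order_factors
        Factor name -> indicators loading on it; each indicator belongs to
        exactly one factor in this pattern.
    second_order_factor
        Name of a single exogenous factor above the first-order factors, or
        None for a correlated-factors model.
    identification
        "equal_gamma" (second-order paths constrained equal — the only
        identified choice with two first-order factors), "free_gamma", or
        "correlated" (no second-order factor; factor correlations free).
    error_covariances
        Indicator pairs whose measurement errors may covary.
    cross_loadings
        Extra (indicator, factor) loadings beyond the simple-structure
        pattern.
    """

    observed: tuple[str, ...]
    first_order_factors: Mapping[str, tuple[str, ...]]
    second_order_factor: str | None = None
    identification: str = "correlated"
    error_covariances: frozenset[tuple[str, str]] = frozenset()
    cross_loadings: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self,
            "first_order_factors",
            {f: tuple(inds) for f, inds in self.first_order_factors.items()},
        )
        object.__setattr__(self, "observed", tuple(self.observed))
        object.__setattr__(
            self,
            "error_covariances",
            frozenset(_canonical_pair(*p) for p in self.error_covariances),
        )
        object.__setattr__(self, "cross_loadings", frozenset(tuple(p) for p in self.cross_loadings))
        if self.identification not in _IDENTIFICATIONS:
            raise ValueError(f"unknown identification {self.identification!r}")
        if self.second_order_factor is None and self.identification != "correlated":
            raise ValueError("gamma identifications require a second-order factor")
        if self.second_order_factor is not None and self.identification == "correlated":
            raise ValueError("'correlated' identification excludes a second-order factor")
        assigned: dict[str, str] = {}
        for factor, inds in self.first_order_factors.items():
            for ind in inds:
                if ind not in self.observed:
                    raise ValueError(f"indicator {ind!r} not among observed")
                if ind in assigned:
                    raise ValueError(f"indicator {ind!r} assigned to two factors")
                assigned[ind] = factor
        missing = set(self.observed) - set(assigned)
        if missing:
            raise ValueError(f"indicators with no factor: {sorted(missing)}")
        for a, b in self.error_covariances:
            if a not in self.observed or b not in self.observed:
                raise ValueError(f"error covariance ({a}, {b}) names unknown indicator")
        for ind, factor in self.cross_loadings:
            if factor not in self.first_order_factors:
                raise ValueError(f"cross-loading names unknown factor {factor!r}")
            if ind in self.first_order_factors[factor]:
                raise ValueError(f"cross-loading ({ind}, {factor}) already in the pattern")
        p = len(self.observed)
        if self.q > p * (p + 1) // 2:
            raise ValueError(
                f"parameter count q={self.q} exceeds the p(p+1)/2={p * (p + 1) // 2} "
                "sample moments; model cannot be identified"
            )

    # ------------------------------------------------------------------ sizes
    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.first_order_factors)

    @property
    def loading_entries(self) -> tuple[tuple[str, str], ...]:
        pattern = [
            (ind, factor)
            for factor in self.factor_names
            for ind in self.first_order_factors[factor]
        ]
        return tuple(pattern) + tuple(sorted(self.cross_loadings))

    @property
    def n_factor_params(self) -> int:
        m = len(self.factor_names)
        if m == 1:
            return 0
        if self.identification == "equal_gamma":
            return 1
        if self.identification == "free_gamma":
            return m
        return m * (m - 1) // 2

    @property
    def q(self) -> int:
        """Number of free parameters."""
        return (
            len(self.loading_entries)
            + self.n_factor_params
            + len(self.observed)
            + len(self.error_covariances)
        )

    @property
    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.q

    # ------------------------------------------------------------- derivation
    def with_error_covariance(self, a: str, b: str) -> "CfaModelSpec":
        pair = _canonical_pair(a, b)
        if pair in self.error_covariances:
            raise ValueError(f"error covariance {pair} is already free")
        return replace(self, error_covariances=self.error_covariances | {pair})

    def with_cross_loading(self, indicator: str, factor: str) -> "CfaModelSpec":
        entry = (indicator, factor)
        if entry in self.cross_loadings or indicator in self.first_order_factors.get(factor, ()):
            raise ValueError(f"loading {entry} is already free")
        return replace(self, cross_loadings=self.cross_loadings | {entry})

    def to_dict(self) -> dict:
        """Plain-data form for YAML/JSON serialization."""
        return {
            "observed": list(self.observed),
            "first_order_factors": {f: list(v) for f, v in self.first_order_factors.items()},
            "second_order_factor": self.second_order_factor,
            "identification": self.identification,
            "error_covariances": sorted(list(p) for p in self.error_covariances),
            "cross_loadings": sorted(list(p) for p in self.cross_loadings),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CfaModelSpec":
        return cls(
            observed=tuple(data["observed"]),
            first_order_factors={f: tuple(v) for f, v in data["first_order_factors"].items()},
            second_order_factor=data.get("second_order_factor"),
            identification=data.get("identification", "correlated"),
            error_covariances=frozenset(tuple(p) for p in data.get("error_covariances", [])),
            cross_loadings=frozenset(tuple(p) for p in data.get("cross_loadings", [])),
        )


def build_default_model() -> CfaModelSpec:
    """Two first-order nutrient factors under one second-order fertility factor.

    Total nutrients are measured by SOM, TN and TP; available nutrients by
    AN, AP and AK.  With only two first-order factors the second-order paths
    are identified by constraining them equal (the factor correlation they
    imply, gamma^2, is the single estimable quantity).
    """
    return CfaModelSpec(
        observed=INDICATORS,
        first_order_factors={
            "TotalNutrients": ("som", "tn", "tp"),
            "AvailableNutrients": ("an", "ap", "ak"),
        },
        second_order_factor="SoilFertility",
        identification="equal_gamma",
    )


def correlated_factors_model() -> CfaModelSpec:
    """The same measurement model with a free factor correlation instead of a
    second-order factor; used as simulation truth (correlation = gamma1*gamma2)."""
    return CfaModelSpec(
        observed=INDICATORS,
        first_order_factors={
            "TotalNutrients": ("som", "tn", "tp"),
            "AvailableNutrients": ("an", "ap", "ak"),
        },
        second_order_factor=None,
        identification="correlated",
    )


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


class _Engine:
    """Maps the free-parameter vector to Sigma(theta) and its gradient."""

    def __init__(self, spec: CfaModelSpec):
        self.spec = spec
        self.p = len(spec.observed)
        self.m = len(spec.factor_names)
        self.obs_index = {name: i for i, name in enumerate(spec.observed)}
        self.fac_index = {name: i for i, name in enumerate(spec.factor_names)}
        self.load_ij = [
            (self.obs_index[ind], self.fac_index[fac]) for ind, fac in spec.loading_entries
        ]
        self.cov_ij = [
            (self.obs_index[a], self.obs_index[b]) for a, b in sorted(spec.error_covariances)
        ]
        self.n_load = len(self.load_ij)
        self.n_fac = spec.n_factor_params
        self.n_var = self.p
        self.n_cov = len(self.cov_ij)
        self.sl = slice(0, self.n_load)
        self.sf = slice(self.n_load, self.n_load + self.n_fac)
        self.sv = slice(self.sf.stop, self.sf.stop + self.n_var)
        self.sc = slice(self.sv.stop, self.sv.stop + self.n_cov)
        self.q = self.sc.stop
        if self.m > 1 and spec.identification == "correlated":
            self.phi_pairs = [(h, g) for h in range(self.m) for g in range(h + 1, self.m)]
        else:
            self.phi_pairs = []

    # -- parameter unpacking -------------------------------------------------
    def unpack(self, theta):
        lam = np.zeros((self.p, self.m))
        for val, (i, h) in zip(theta[self.sl], self.load_ij):
            lam[i, h] += val
        phi = np.eye(self.m)
        fpars = np.asarray(theta[self.sf])
        if self.m > 1:
            if self.spec.identification == "equal_gamma":
                g = fpars[0]
                phi = np.full((self.m, self.m), g * g)
                np.fill_diagonal(phi, 1.0)
            elif self.spec.identification == "free_gamma":
                phi = np.outer(fpars, fpars)
                np.fill_diagonal(phi, 1.0)
            else:
                for val, (h, g) in zip(fpars, self.phi_pairs):
                    phi[h, g] = phi[g, h] = val
        theta_mat = np.diag(np.asarray(theta[self.sv], dtype=float))
        for val, (i, j) in zip(theta[self.sc], self.cov_ij):
            theta_mat[i, j] = theta_mat[j, i] = val
        return lam, phi, theta_mat

    def sigma(self, theta):
        lam, phi, theta_mat = self.unpack(theta)
        return lam @ phi @ lam.T + theta_mat

    def gamma_values(self, theta) -> np.ndarray:
        fpars = np.asarray(theta[self.sf])
        if self.spec.identification == "equal_gamma":
            return np.full(self.m, fpars[0])
        if self.spec.identification == "free_gamma":
            return fpars.copy()
        raise ValueError("no second-order paths in a correlated-factors model")

    # -- discrepancy ---------------------------------------------------------
    def fml_and_grad(self, theta, S, logdet_S):
        lam, phi, theta_mat = self.unpack(theta)
        sigma = lam @ phi @ lam.T + theta_mat
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or not np.isfinite(logdet):
            return 1e10, np.zeros(self.q)
        sig_inv = np.linalg.inv(sigma)
        f = logdet - logdet_S + float(np.sum(sig_inv * S)) - self.p
        # dF = tr(A dSigma) with A = Sigma^-1 - Sigma^-1 S Sigma^-1
        A = sig_inv - sig_inv @ S @ sig_inv
        grad = np.empty(self.q)
        ALP = A @ lam @ phi  # p x m
        for k, (i, h) in enumerate(self.load_ij):
            grad[k] = 2.0 * ALP[i, h]
        if self.n_fac:
            LAL = lam.T @ A @ lam  # m x m
            fpars = np.asarray(theta[self.sf])
            if self.spec.identification == "equal_gamma":
                g = fpars[0]
                off = LAL.sum() - np.trace(LAL)
                grad[self.sf] = 2.0 * g * off
            elif self.spec.identification == "free_gamma":
                gvec = fpars
                gr = np.empty(self.m)
                for h in range(self.m):
                    gr[h] = 2.0 * sum(
                        gvec[g] * LAL[h, g] for g in range(self.m) if g != h
                    )
                grad[self.sf] = gr
            else:
                grad[self.sf] = [2.0 * LAL[h, g] for h, g in self.phi_pairs]
        grad[self.sv] = np.diag(A)
        for k, (i, j) in enumerate(self.cov_ij):
            grad[self.sc.start + k] = 2.0 * A[i, j]
        return float(f), grad

    # -- starting values -----------------------------------------------------
    def start(self, rng: np.random.Generator | None = None):
        x0 = np.empty(self.q)
        n_pattern = self.n_load - len(self.spec.cross_loadings)
        x0[self.sl] = [0.7] * n_pattern + [0.1] * len(self.spec.cross_loadings)
        if self.n_fac:
            x0[self.sf] = 0.6 if self.spec.identification != "correlated" else 0.3
        x0[self.sv] = 0.5
        x0[self.sc] = 0.0
        if rng is not None:
            x0[self.sl] += rng.uniform(-0.2, 0.2, self.n_load)
            if self.n_fac:
                x0[self.sf] = np.clip(
                    x0[self.sf] + rng.uniform(-0.3, 0.3, self.n_fac), -0.9, 0.9
                )
            x0[self.sv] = np.clip(x0[self.sv] + rng.uniform(-0.3, 0.5, self.n_var), 0.05, None)
        return x0

    def bounds(self):
        b: list[tuple[float | None, float | None]] = []
        b += [(-10.0, 10.0)] * self.n_load
        if self.n_fac:
            b += [(-0.999, 0.999)] * self.n_fac
        b += [(ERROR_VARIANCE_FLOOR, None)] * self.n_var
        b += [(-10.0, 10.0)] * self.n_cov
        return b


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class CfaFit:
    """Converged ML solution for one model/data pair.

    ``theta`` is on the correlation (standardized-observed) scale used
    internally; ``loadings`` / ``error_variances`` report the input scale.
    """

    spec: CfaModelSpec
    theta: np.ndarray
    sigma_hat: np.ndarray
    sample_cov: np.ndarray
    n: int
    fmin: float
    chi2: float
    df: int
    loadings: dict[tuple[str, str], float]
    std_loadings: dict[tuple[str, str], float]
    std_gamma: dict[str, float]
    factor_corr: np.ndarray
    error_variances: dict[str, float]
    error_covariances: dict[tuple[str, str], float]
    smc: dict[str, float]
    converged: bool
    grad_norm: float
    heywood: bool
    n_starts_used: int = 1

    @property
    def cmin_df(self) -> float:
        return self.chi2 / self.df if self.df > 0 else float("nan")

    def std_loading_list(self, order: Sequence[str] | None = None) -> list[float]:
        """Standardized pattern loadings in indicator order (simple structure)."""
        order = order if order is not None else self.spec.observed
        pattern = {ind: fac for fac, inds in self.spec.first_order_factors.items() for ind in inds}
        return [self.std_loadings[(ind, pattern[ind])] for ind in order]

    def to_frame(self) -> pd.DataFrame:
        """Parameter report: unstandardized and standardized estimates + SMC."""
        rows = []
        for (ind, fac), val in self.loadings.items():
            rows.append(
                (f"{fac} -> {ind}", "loading", val, self.std_loadings[(ind, fac)],
                 self.smc.get(ind, np.nan))
            )
        for fac, val in self.std_gamma.items():
            rows.append(
                (f"{self.spec.second_order_factor} -> {fac}", "gamma", val, val,
                 self.smc.get(fac, np.nan))
            )
        if self.spec.identification == "correlated" and len(self.spec.factor_names) > 1:
            names = self.spec.factor_names
            for h in range(len(names)):
                for g in range(h + 1, len(names)):
                    rows.append(
                        (f"{names[h]} <-> {names[g]}", "factor_corr",
                         self.factor_corr[h, g], self.factor_corr[h, g], np.nan)
                    )
        for ind, val in self.error_variances.items():
            rows.append((f"err({ind})", "error_variance", val, np.nan, np.nan))
        for (a, b), val in self.error_covariances.items():
            rows.append((f"err({a}) <-> err({b})", "error_covariance", val, np.nan, np.nan))
        rows.append(("chi2", "fit", self.chi2, np.nan, np.nan))
        rows.append(("df", "fit", self.df, np.nan, np.nan))
        return pd.DataFrame(
            rows, columns=["parameter", "kind", "unstandardized", "standardized", "smc"]
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _sample_cov(data, spec: CfaModelSpec) -> tuple[np.ndarray, int]:
    if isinstance(data, pd.DataFrame):
        x = data[list(spec.observed)].to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(spec.observed):
        raise ValueError("data must be n x p for the spec's observed indicators")
    return np.cov(x, rowvar=False, ddof=1), x.shape[0]


def fit_cfa(
    spec: CfaModelSpec,
    data=None,
    *,
    sample_cov=None,
    n: int | None = None,
    max_starts: int = 5,
    seed: int = 0,
    _x0=None,
) -> CfaFit:
    """Fit the model by minimizing the ML discrepancy.

    Supply either ``data`` (rows x indicators, DataFrame or array) or a
    precomputed ``sample_cov`` with its sample size ``n``.  On
    non-convergence the optimizer is restarted from up to ``max_starts``
    jittered starting points; a Heywood case (error variance at its floor)
    is clamped and flagged with a warning rather than raised.
    """
    if (data is None) == (sample_cov is None):
        raise ValueError("supply exactly one of data or sample_cov")
    if data is not None:
        S, n = _sample_cov(data, spec)
    else:
        S = np.asarray(sample_cov, dtype=float)
        if n is None:
            raise ValueError("n is required with sample_cov")
    p = len(spec.observed)
    if S.shape != (p, p):
        raise ValueError(f"sample covariance must be {p} x {p}")
    if n <= p:
        raise ValueError("sample size must exceed the number of indicators")
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise SingularMatrixError("sample covariance is not positive definite")

    # fit on the correlation scale; the model family is diagonal-scale invariant
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    _, logdet_R = np.linalg.slogdet(R)

    engine = _Engine(spec)
    rng = np.random.default_rng(seed)
    starts = [engine.start()] if _x0 is None else [np.asarray(_x0, dtype=float)]
    starts += [engine.start(rng) for _ in range(max_starts - 1)]
    bounds = engine.bounds()

    best = None
    last_grad = float("nan")
    used = 0
    for x0 in starts:
        used += 1
        res = minimize(
            engine.fml_and_grad,
            x0,
            args=(R, logdet_R),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-9},
        )
        _, grad = engine.fml_and_grad(res.x, R, logdet_R)
        grad_norm = float(np.linalg.norm(grad, ord=np.inf))
        # at active bounds (Heywood clamp) the raw gradient need not vanish;
        # project it onto the feasible directions
        proj = grad.copy()
        for k, (lo, hi) in enumerate(bounds):
            if lo is not None and res.x[k] <= lo + 1e-12 and proj[k] > 0:
                proj[k] = 0.0
            if hi is not None and res.x[k] >= hi - 1e-12 and proj[k] < 0:
                proj[k] = 0.0
        proj_norm = float(np.linalg.norm(proj, ord=np.inf))
        last_grad = proj_norm
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.copy(), proj_norm, grad_norm)
        if proj_norm < GRAD_TOL:
            best = (float(res.fun), res.x.copy(), proj_norm, grad_norm)
            break
    assert best is not None
    fmin, theta, proj_norm, _ = best
    if proj_norm >= GRAD_TOL:
        raise NotConvergedError(
            f"optimizer did not reach a stationary point after {used} start(s); "
            f"projected gradient norm {proj_norm:.3g}",
            grad_norm=last_grad,
        )

    fmin = max(fmin, 0.0)
    lam_R, phi, theta_mat_R = engine.unpack(theta)
    sigma_R = lam_R @ phi @ lam_R.T + theta_mat_R
    sd_hat = np.sqrt(np.diag(sigma_R))

    heywood = bool(np.any(theta[engine.sv] <= ERROR_VARIANCE_FLOOR + 1e-12))
    if heywood:
        warnings.warn(
            "Heywood case: error variance clamped at the admissibility floor",
            RuntimeWarning,
            stacklevel=2,
        )

    # each (indicator, factor) slot carries exactly one free parameter, and
    # latent variances are fixed at 1, so standardizing only rescales by the
    # implied observed SD
    std_loadings = {}
    loadings = {}
    for k, (ind, fac) in enumerate(spec.loading_entries):
        i, _h = engine.load_ij[k]
        raw = float(theta[engine.sl][k])
        std_loadings[(ind, fac)] = raw / float(sd_hat[i])
        loadings[(ind, fac)] = raw * float(d[i])

    std_gamma = {}
    if spec.second_order_factor is not None and engine.m > 1:
        gam = engine.gamma_values(theta)
        std_gamma = {fac: float(gam[h]) for h, fac in enumerate(spec.factor_names)}

    smc = {}
    for i, ind in enumerate(spec.observed):
        smc[ind] = float(1.0 - theta_mat_R[i, i] / sigma_R[i, i])
    for fac, g in std_gamma.items():
        smc[fac] = float(g * g)

    error_variances = {
        ind: float(theta[engine.sv][i] * d[i] ** 2) for i, ind in enumerate(spec.observed)
    }
    error_covs = {}
    for k, (a, b) in enumerate(sorted(spec.error_covariances)):
        i, j = engine.cov_ij[k]
        error_covs[(a, b)] = float(theta[engine.sc][k] * d[i] * d[j])

    sigma_hat = sigma_R * np.outer(d, d)
    chi2 = float((n - 1) * fmin)
    return CfaFit(
        spec=spec,
        theta=np.asarray(theta, dtype=float),
        sigma_hat=sigma_hat,
        sample_cov=S,
        n=int(n),
        fmin=float(fmin),
        chi2=chi2,
        df=spec.df,
        loadings=loadings,
        std_loadings=std_loadings,
        std_gamma=std_gamma,
        factor_corr=phi,
        error_variances=error_variances,
        error_covariances=error_covs,
        smc=smc,
        converged=True,
        grad_norm=proj_norm,
        heywood=heywood,
        n_starts_used=used,
    )


def squared_multiple_correlation(fit: CfaFit) -> dict[str, float]:
    """SMC per observed indicator (and per first-order factor if a
    second-order factor is present): the share of variance explained by the
    latent side of the model.  For simple structure without correlated errors
    an indicator's SMC equals its squared standardized loading; a first-order
    factor's SMC equals its squared standardized gamma path."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return dict(fit.smc)


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------


def default_candidates(spec: CfaModelSpec) -> list[tuple]:
    """All currently-fixed error covariances and cross-loadings."""
    cands: list[tuple] = []
    obs = spec.observed
    for i in range(len(obs)):
        for j in range(i + 1, len(obs)):
            pair = _canonical_pair(obs[i], obs[j])
            if pair not in spec.error_covariances:
                cands.append(("error_covariance", *pair))
    pattern = {ind: fac for fac, inds in spec.first_order_factors.items() for ind in inds}
    for ind in obs:
        for fac in spec.factor_names:
            if pattern[ind] != fac and (ind, fac) not in spec.cross_loadings:
                cands.append(("cross_loading", ind, fac))
    return cands


def modification_indices(
    fit: CfaFit,
    candidates: Sequence[tuple] | None = None,
) -> list[tuple[tuple, float]]:
    """Exact (refit-based) modification indices, sorted descending.

    For each candidate fixed parameter — ``("error_covariance", a, b)`` or
    ``("cross_loading", indicator, factor)`` — the model is refit with that
    single parameter freed, warm-started from the current solution, and the
    chi-square decrease is reported.  Freeing the top candidate and refitting
    therefore reproduces ``old_chi2 - MI`` by construction.
    """
    spec = fit.spec
    if candidates is None:
        candidates = default_candidates(spec)
    engine = _Engine(spec)
    results = []
    for cand in candidates:
        kind, a, b = cand
        if kind == "error_covariance":
            if _canonical_pair(a, b) in spec.error_covariances:
                raise ValueError(f"candidate {cand} is already a free parameter")
            new_spec = spec.with_error_covariance(a, b)
        elif kind == "cross_loading":
            if (a, b) in spec.cross_loadings:
                raise ValueError(f"candidate {cand} is already a free parameter")
            new_spec = spec.with_cross_loading(a, b)
        else:
            raise ValueError(f"unknown candidate kind {kind!r}")
        if new_spec.df < 0:
            continue
        new_engine = _Engine(new_spec)
        x0 = _warm_start(engine, new_engine, fit.theta)
        try:
            new_fit = fit_cfa(
                new_spec,
                sample_cov=fit.sample_cov,
                n=fit.n,
                _x0=x0,
                max_starts=3,
            )
        except NotConvergedError:
            continue
        results.append((cand, max(fit.chi2 - new_fit.chi2, 0.0)))
    results.sort(key=lambda item: -item[1])
    return results


def _warm_start(old: _Engine, new: _Engine, theta_old: np.ndarray) -> np.ndarray:
    """Map a parameter vector into a superset engine; new parameters start at 0."""
    key_old = _param_keys(old)
    key_new = _param_keys(new)
    lookup = dict(zip(key_old, theta_old))
    return np.array([lookup.get(k, 0.0) for k in key_new])


def _param_keys(engine: _Engine) -> list[tuple]:
    keys: list[tuple] = [("load",) + entry for entry in engine.spec.loading_entries]
    keys += [("fac", i) for i in range(engine.n_fac)]
    keys += [("var", name) for name in engine.spec.observed]
    keys += [("cov",) + pair for pair in sorted(engine.spec.error_covariances)]
    return keys
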