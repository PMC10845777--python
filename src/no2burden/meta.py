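"""Stage 2: random-effects pooling of county effect estimates.

County log-relative-risks per 10 ug/m3 are pooled with an inverse-variance
random-effects model (REML between-county variance by default,
DerSimonian-Laird as an option and fallback), transformed to percentage
change, contrasted between urban and rural strata with a normal two-sample
Z test, regressed on county-level moderators, and - for the nonlinear
concentration-response analysis - pooled as whole spline coefficient
vectors (meta-smoothing).

All Wald intervals use the standard normal reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .county import EffectEstimate

__all__ = [
    "PooledEffect",
    "DifferenceTest",
    "RandomEffectsMeta",
    "MetaResults",
    "pool_random_effects",
    "percentage_change",
    "ci_to_log_scale",
    "urban_rural_test",
    "MetaRegression",
    "MetaRegressionResults",
    "pool_curves",
]

Z975 = stats.norm.ppf(0.975)


def percentage_change(beta: float, se: float) -> tuple[float, float, float]:
    """Percentage change per 10 ug/m3 with its 95% CI: (e^beta - 1) x 100,
    endpoints from beta -/+ 1.96 se."""
    if not (np.isfinite(beta) and np.isfinite(se)):
        raise ValueError("beta and se must be finite")
    pct = (np.exp(beta) - 1.0) * 100.0
    lo = (np.exp(beta - Z975 * se) - 1.0) * 100.0
    hi = (np.exp(beta + Z975 * se) - 1.0) * 100.0
    return float(pct), float(lo), float(hi)


def ci_to_log_scale(pct: float, lo: float, hi: float) -> tuple[float, float]:
    """Invert a printed percentage change and 95% CI back to (beta, se)."""
    if not (lo < pct < hi):
        raise ValueError(f"CI ({lo}, {hi}) does not bracket the point {pct}")
    if min(pct, lo, hi) <= -100:
        raise ValueError("percentage changes must exceed -100")
    beta = np.log1p(pct / 100.0)
    se = (np.log1p(hi / 100.0) - np.log1p(lo / 100.0)) / (2.0 * Z975)
    return float(beta), float(se)


@dataclass
class PooledEffect:
    """Stratum-level pooled effect on the per-10 ug/m3 log-RR scale."""

    stratum: str
    cause: str
    lag: str
    beta: float
    se: float
    tau2: float
    i2: float                   # percent, in [0, 100]
    k: int
    degenerate: bool = False    # single-county stratum

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z975 * self.se, self.beta + Z975 * self.se)

    @property
    def pct(self) -> tuple[float, float, float]:
        return percentage_change(self.beta, self.se)


@dataclass
class DifferenceTest:
    """Normal two-sample contrast of urban vs rural pooled log-RRs."""

    cause: str
    lag: str
    e_urban: float
    e_rural: float
    se_urban: float
    se_rural: float
    z: float
    p: float


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird method-of-moments between-study variance."""
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    k = len(y)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0


def _reml_neg_llf(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


def _reml_tau2(y: np.ndarray, v: np.ndarray, maxiter: int = 200) -> float:
    hi = max(10.0 * np.var(y), v.max(), 1e-8)
    res = optimize.minimize_scalar(
        _reml_neg_llf,
        bounds=(0.0, hi),
        args=(y, v),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": maxiter},
    )
    if not res.success or not np.isfinite(res.x):
        warnings.warn("REML tau2 failed to converge; falling back to DL")
        return _dl_tau2(y, v)
    return float(max(0.0, res.x))


class RandomEffectsMeta:
    """Random-effects meta-analysis model over (estimate, SE) pairs."""

    def __init__(self, betas, ses):
        self.y = np.asarray(betas, dtype=float)
        self.se = np.asarray(ses, dtype=float)
        if len(self.y) == 0:
            raise ValueError("no estimates to pool")
        if np.any(self.se <= 0):
            raise ValueError("all standard errors must be positive")

    def fit(self, method: str = "reml") -> "MetaResults":
        y, v = self.y, self.se**2
        k = len(y)
        if k == 1:
            return MetaResults(
                beta=float(y[0]), se=float(self.se[0]), tau2=0.0, i2=0.0,
                q=0.0, k=1, method=method, degenerate=True,
            )
        if method == "fixed":
            tau2 = 0.0
        elif method == "dl":
            tau2 = _dl_tau2(y, v)
        elif method == "reml":
            tau2 = _reml_tau2(y, v)
        else:
            raise ValueError(f"unknown pooling method {method!r}")
        w = 1.0 / (v + tau2)
        beta = np.sum(w * y) / np.sum(w)
        se = np.sqrt(1.0 / np.sum(w))
        # heterogeneity from the fixed-effect Q statistic
        w0 = 1.0 / v
        mu0 = np.sum(w0 * y) / np.sum(w0)
        q = float(np.sum(w0 * (y - mu0) ** 2))
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
        return MetaResults(
            beta=float(beta), se=float(se), tau2=float(tau2), i2=float(i2),
            q=q, k=k, method=method,
        )


@dataclass
class MetaResults:
    beta: float
    se: float
    tau2: float
    i2: float
    q: float
    k: int
    method: str
    degenerate: bool = False

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z975 * self.se, self.beta + Z975 * self.se)

    def summary(self) -> str:
        pct, lo, hi = percentage_change(self.beta, self.se)
        return (
            f"Random-effects meta-analysis ({self.method}, k={self.k})\n"
            f"  pooled log-RR/10ug: {self.beta:.5f} (SE {self.se:.5f})\n"
            f"  pct change: {pct:.2f}% (95% CI {lo:.2f} to {hi:.2f})\n"
            f"  tau2={self.tau2:.3e}  I2={self.i2:.1f}%  Q={self.q:.2f}"
        )


def pool_random_effects(
    estimates: list[EffectEstimate],
    stratum: str = "overall",
    method: str = "reml",
) -> PooledEffect:
    """Pool county effect estimates for one (cause, lag) cell.

    A single estimate is passed through with ``tau2 = 0`` and a
    ``degenerate`` flag; an empty list is an error.
    """
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty set of estimates")
    causes = {e.cause for e in estimates}
    lags = {e.lag for e in estimates}
    if len(causes) > 1 or len(lags) > 1:
        raise ValueError(f"mixed cells: causes {causes}, lags {lags}")
    res = RandomEffectsMeta([e.beta for e in estimates], [e.se for e in estimates]).fit(
        method=method
    )
    return PooledEffect(
        stratum=stratum,
        cause=causes.pop(),
        lag=lags.pop(),
        beta=res.beta,
        se=res.se,
        tau2=res.tau2,
        i2=res.i2,
        k=res.k,
        degenerate=res.degenerate,
    )


def urban_rural_test(pooled_urban: PooledEffect, pooled_rural: PooledEffect) -> DifferenceTest:
    """Two-sample normal test of the urban-rural difference in pooled
    log-RRs: Z = (E_u - E_r) / sqrt(SE_u^2 + SE_r^2)."""
    if (pooled_urban.cause, pooled_urban.lag) != (pooled_rural.cause, pooled_rural.lag):
        raise ValueError(
            f"mismatched cells: urban ({pooled_urban.cause}, {pooled_urban.lag}) "
            f"vs rural ({pooled_rural.cause}, {pooled_rural.lag})"
        )
    z = (pooled_urban.beta - pooled_rural.beta) / np.sqrt(
        pooled_urban.se**2 + pooled_rural.se**2
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return DifferenceTest(
        cause=pooled_urban.cause,
        lag=pooled_urban.lag,
        e_urban=pooled_urban.beta,
        e_rural=pooled_rural.beta,
        se_urban=pooled_urban.se,
        se_rural=pooled_rural.se,
        z=float(z),
        p=float(min(p, 1.0)),
    )


class MetaRegression:
    """Mixed-effects meta-regression of county effects on moderators.

    The model is y_c = X_c gamma + u_c + e_c with u_c ~ N(0, tau2) and
    e_c ~ N(0, se_c^2); tau2 by REML. An intercept column is added
    automatically.
    """

    def __init__(self, betas, ses, moderators: pd.DataFrame):
        self.y = np.asarray(betas, dtype=float)
        self.v = np.asarray(ses, dtype=float) ** 2
        X = pd.DataFrame(moderators).copy()
        X.insert(0, "intercept", 1.0)
        self.X = X
        k, p = X.shape
        if k <= p + 1:
            raise ValueError(f"k={k} counties cannot support {p} moderator columns")
        if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < p:
            raise ValueError("collinear moderators (including a constant moderator)")

    def _gls(self, tau2: float):
        w = 1.0 / (self.v + tau2)
        Xa = self.X.to_numpy(dtype=float)
        xtw = Xa.T * w
        xtwx_inv = np.linalg.inv(xtw @ Xa)
        gamma = xtwx_inv @ (xtw @ self.y)
        resid = self.y - Xa @ gamma
        return gamma, xtwx_inv, resid, w

    def _neg_reml(self, tau2: float) -> float:
        gamma, xtwx_inv, resid, w = self._gls(tau2)
        sign, logdet = np.linalg.slogdet(np.linalg.inv(xtwx_inv))
        return 0.5 * (
            np.sum(np.log(self.v + tau2)) + logdet + np.sum(w * resid**2)
        )

    def fit(self) -> "MetaRegressionResults":
        hi = max(10.0 * np.var(self.y), self.v.max(), 1e-8)
        res = optimize.minimize_scalar(
            self._neg_reml, bounds=(0.0, hi), method="bounded",
            options={"xatol": 1e-10, "maxiter": 200},
        )
        tau2 = float(max(0.0, res.x)) if res.success else 0.0
        gamma, xtwx_inv, resid, _ = self._gls(tau2)
        se = np.sqrt(np.diag(xtwx_inv))
        z = gamma / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        table = pd.DataFrame(
            {"coef": gamma, "se": se, "z": z, "p": p}, index=self.X.columns
        )
        # residual heterogeneity from the fixed-weight residual Q
        w0 = 1.0 / self.v
        g0, _, r0, _ = self._gls(0.0)
        qe = float(np.sum(w0 * r0**2))
        k, pcol = self.X.shape
        i2_res = max(0.0, (qe - (k - pcol)) / qe) * 100.0 if qe > 0 else 0.0
        return MetaRegressionResults(table=table, tau2=tau2, i2_residual=i2_res, qe=qe)


@dataclass
class MetaRegressionResults:
    table: pd.DataFrame
    tau2: float
    i2_residual: float
    qe: float

    def summary(self) -> str:
        return (
            f"Meta-regression (REML), residual I2={self.i2_residual:.1f}%, "
            f"tau2={self.tau2:.3e}\n{self.table.round(5)}"
        )


def pool_curves(
    fits: list,
    grid: np.ndarray,
    ref: float,
    maxiter: int = 200,
) -> pd.DataFrame:
    """Meta-smooth county concentration-response curves.

    ``fits`` are :class:`~no2burden.county.NonlinearNO2Fit` objects sharing
    one spline basis (same interior and boundary knots). The coefficient
    vectors are pooled under a multivariate random-effects model with a
    scalar tau2 x I between-county covariance (REML); if the REML surface is
    degenerate the pooling falls back to coefficient-wise univariate REML
    with a warning. The pooled curve is centred to log-RR 0 at ``ref``.

    Returns a DataFrame with columns ``no2``, ``logrr``, ``lo``, ``hi``.
    """
    if len(fits) == 0:
        raise ValueError("no county fits to pool")
    first = fits[0]
    for f in fits[1:]:
        if f.knots != first.knots or f.boundary != first.boundary:
            raise ValueError(
                f"basis mismatch: county {f.county_id} has knots {f.knots}, "
                f"boundary {f.boundary}"
            )
    thetas = np.array([f.coef for f in fits])          # k x d
    covs = np.array([f.cov for f in fits])             # k x d x d
    k, d = thetas.shape

    def pooled_at(tau2: float):
        wsum = np.zeros((d, d))
        wy = np.zeros(d)
        for i in range(k):
            wi = np.linalg.inv(covs[i] + tau2 * np.eye(d))
            wsum += wi
            wy += wi @ thetas[i]
        vmu = np.linalg.inv(wsum)
        return vmu @ wy, vmu

    def neg_reml(tau2: float) -> float:
        mu, vmu = pooled_at(tau2)
        ll = 0.0
        for i in range(k):
            si = covs[i] + tau2 * np.eye(d)
            r = thetas[i] - mu
            sign, logdet = np.linalg.slogdet(si)
            ll += logdet + r @ np.linalg.solve(si, r)
        sign, logdet_v = np.linalg.slogdet(np.linalg.inv(vmu))
        return 0.5 * (ll + logdet_v)

    if k == 1:
        mu, vmu = thetas[0], covs[0]
    else:
        scale = float(np.mean([np.trace(c) / d for c in covs]))
        try:
            res = optimize.minimize_scalar(
                neg_reml, bounds=(0.0, 100.0 * scale), method="bounded",
                options={"xatol": 1e-12 * max(scale, 1.0), "maxiter": maxiter},
            )
            if not (res.success and np.isfinite(res.fun)):
                raise FloatingPointError("REML surface degenerate")
            mu, vmu = pooled_at(float(max(0.0, res.x)))
        except (FloatingPointError, np.linalg.LinAlgError):
            warnings.warn(
                "multivariate REML failed; falling back to coefficient-wise pooling"
            )
            mu = np.empty(d)
            var = np.empty(d)
            for j in range(d):
                r = RandomEffectsMeta(
                    thetas[:, j], np.sqrt(covs[:, j, j])
                ).fit(method="reml")
                mu[j], var[j] = r.beta, r.se**2
            vmu = np.diag(var)

    grid = np.asarray(grid, dtype=float)
    b = first.basis.evaluate(grid) - first.basis.evaluate(np.array([float(ref)]))
    curve = b @ mu
    var = np.einsum("ij,jk,ik->i", b, vmu, b)
    half = Z975 * np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {"no2": grid, "logrr": curve, "lo": curve - half, "hi": curve + half}
    )
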