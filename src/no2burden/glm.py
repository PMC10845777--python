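"""Overdispersed Poisson regression via IRLS.

Point estimates are Poisson maximum-likelihood; standard errors are the
Poisson information SEs inflated by the square root of the Pearson
dispersion (the quasi-Poisson convention for overdispersed count series).
statsmodels' GLM supplies the IRLS machinery; this module fixes the family,
the dispersion scaling and the error contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["QPFit", "ConvergenceError", "fit_quasi_poisson"]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass
class QPFit:
    params: pd.Series
    cov: pd.DataFrame          # dispersion-scaled coefficient covariance
    dispersion: float          # Pearson chi2 / (n - p)
    deviance: float
    n_obs: int
    df_resid: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via pivoted QR on the scaled design
        scaled = arr / np.maximum(np.abs(arr).max(axis=0), 1e-300)
        r = np.linalg.qr(scaled, mode="r")
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-9 * diag.max())[0]]
        raise ValueError(
            f"design matrix rank {rank} < {arr.shape[1]} columns; "
            f"collinear columns include {bad or 'unidentified set'}"
        )


def fit_quasi_poisson(
    y,
    X: pd.DataFrame,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> QPFit:
    """Fit a log-link quasi-Poisson regression of counts ``y`` on ``X``.

    ``X`` must include its own intercept column and be full column rank;
    ``y`` must be nonnegative. Raises :class:`ConvergenceError` if IRLS does
    not converge and ``ValueError`` on rank deficiency (naming the collinear
    columns).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("admission counts must be nonnegative")
    X = pd.DataFrame(X)
    _check_rank(X)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol)
    if not res.converged:
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(final deviance {res.deviance:.6g})"
        )
    n, p = X.shape
    # Pearson dispersion applied post-fit (the quasi-Poisson SE inflation);
    # statsmodels' scale='X2' is avoided because it breaks on perfect fits
    pearson = float(np.sum((y - res.mu) ** 2 / res.mu))
    dispersion = pearson / (n - p) if n > p else 0.0
    cov = np.asarray(res.cov_params()) * dispersion
    return QPFit(
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        dispersion=dispersion,
        deviance=float(res.deviance),
        n_obs=n,
        df_resid=n - p,
    )
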