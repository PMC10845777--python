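"""Stage 1: county-level distributed-lag models of NO2 and admissions.

:class:`CountyNO2Model` is the modelling entry point: it is constructed from
one county's day-indexed panel, assembles the confounder design (calendar
spline at 7 df per year, day-of-week and holiday indicators, natural splines
in 3-day moving-average temperature at 6 df and relative humidity at 3 df),
enters the exposure under a :class:`~no2burden.design.LagSpec`, and its
``fit()`` returns a :class:`CountyNO2Results` carrying the quasi-Poisson
fit, the per-10 ug/m3 effect estimates, and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import LagSpec, calendar_design, lag_matrix, moving_average, ns_basis
from .glm import QPFit, fit_quasi_poisson

__all__ = [
    "ConfounderConfig",
    "EffectEstimate",
    "CountyExcludedError",
    "CountyNO2Model",
    "CountyNO2Results",
    "NonlinearNO2Fit",
    "fit_county_dlm",
    "fit_nonlinear_no2",
]

MIN_USABLE_DAYS = 365


class CountyExcludedError(RuntimeError):
    """County series too short to fit; the pipeline records the exclusion."""


@dataclass(frozen=True)
class ConfounderConfig:
    """Degrees of freedom for the confounder adjustment."""

    time_df_per_year: float = 7.0
    temp_df: int = 6
    rh_df: int = 3
    ma_window: int = 3          # trailing window for temperature/humidity


@dataclass
class EffectEstimate:
    """A log-relative-risk per 10 ug/m3 NO2 with its standard error."""

    county_id: str
    cause: str
    lag: str                    # "lag0", "lag0-4 cumulative", "lag0-1 MA", ...
    beta: float                 # log-RR per 10 ug/m3
    se: float
    zone: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError(f"non-finite effect estimate for {self.county_id}")
        if not self.se > 0:
            raise ValueError(f"standard error must be positive, got {self.se}")


class CountyNO2Model:
    """Quasi-Poisson distributed-lag model for one county and cause.

    Parameters
    ----------
    data : DataFrame with columns ``date``, ``admissions``, ``no2``,
        ``temp``, ``rh``, ``holiday`` (and the co-pollutant column when a
        two-pollutant model is requested), one row per consecutive day.
    lag : exposure lag structure; ``single`` enters lags 0..max_lag jointly
        (the distributed-lag model), ``moving_average`` enters one trailing
        mean column.
    copollutant : optional column name entered linearly at lag 0.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        county_id: str = "county",
        cause: str = "cvd",
        zone: str | None = None,
        lag: LagSpec = LagSpec("single", 4),
        confounders: ConfounderConfig = ConfounderConfig(),
        copollutant: str | None = None,
    ):
        self.data = data.reset_index(drop=True)
        self.county_id = county_id
        self.cause = cause
        self.zone = zone
        self.lag = lag
        self.confounders = confounders
        self.copollutant = copollutant
        n_drop = max(lag.max_lag, confounders.ma_window - 1)
        if len(self.data) - n_drop < MIN_USABLE_DAYS:
            raise CountyExcludedError(
                f"county {county_id}: {len(self.data) - n_drop} usable days "
                f"after lag trimming, need >= {MIN_USABLE_DAYS}"
            )
        self._n_drop = n_drop

    def _build_design(self) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
        d = self.data
        cfg = self.confounders
        exposure, _ = lag_matrix(d["no2"], self.lag)
        exposure_cols = list(exposure.columns)

        cal = calendar_design(pd.DatetimeIndex(d["date"]), holidays=d["holiday"])
        cal.index = d.index

        keep = slice(self._n_drop, None)
        temp_ma = moving_average(d["temp"], cfg.ma_window)[keep]
        rh_ma = moving_average(d["rh"], cfg.ma_window)[keep]
        temp_b = ns_basis(temp_ma.to_numpy(), cfg.temp_df)
        rh_b = ns_basis(rh_ma.to_numpy(), cfg.rh_df)

        parts = [
            pd.DataFrame({"intercept": np.ones(len(d))}, index=d.index)[keep],
            exposure[keep],
            cal[keep],
            pd.DataFrame(
                temp_b.matrix,
                columns=[f"temp_ns{j + 1}" for j in range(cfg.temp_df)],
                index=d.index[keep],
            ),
            pd.DataFrame(
                rh_b.matrix,
                columns=[f"rh_ns{j + 1}" for j in range(cfg.rh_df)],
                index=d.index[keep],
            ),
        ]
        if self.copollutant is not None:
            parts.append(d[[self.copollutant]].iloc[keep])
        X = pd.concat(parts, axis=1)
        y = d["admissions"].to_numpy()[keep]
        return y, X, exposure_cols

    def fit(self) -> "CountyNO2Results":
        y, X, exposure_cols = self._build_design()
        qp = fit_quasi_poisson(y, X)
        return CountyNO2Results(self, qp, exposure_cols)


class CountyNO2Results:
    """Fitted county model: coefficient table plus per-10 effect extraction."""

    def __init__(self, model: CountyNO2Model, qpfit: QPFit, exposure_cols: list[str]):
        self.model = model
        self.qpfit = qpfit
        self.exposure_cols = exposure_cols

    @property
    def dispersion(self) -> float:
        return self.qpfit.dispersion

    @property
    def nobs(self) -> int:
        return self.qpfit.n_obs

    def _estimate(self, lag_label: str, contrast: np.ndarray) -> EffectEstimate:
        idx = [self.qpfit.params.index.get_loc(c) for c in self.exposure_cols]
        beta_block = self.qpfit.params.iloc[idx].to_numpy()
        v_block = self.qpfit.cov.iloc[idx, idx].to_numpy()
        beta = 10.0 * float(contrast @ beta_block)
        se = 10.0 * float(np.sqrt(contrast @ v_block @ contrast))
        return EffectEstimate(
            county_id=self.model.county_id,
            cause=self.model.cause,
            lag=lag_label,
            beta=beta,
            se=se,
            zone=self.model.zone,
        )

    def effects(self) -> list[EffectEstimate]:
        """Single-day effects for each lag plus cumulative effects 0..k.

        The cumulative 0..k estimate is 10 x the sum of the first k+1 lag
        coefficients, with variance 1' V 1 over that block; cumulative 0..0
        therefore equals the single-day lag-0 estimate exactly.
        """
        m = len(self.exposure_cols)
        if self.model.lag.kind == "moving_average":
            return [self._estimate(self.model.lag.label, np.ones(1))]
        out = []
        for l in range(m):
            e = np.zeros(m)
            e[l] = 1.0
            out.append(self._estimate(f"lag{l}", e))
        for k in range(1, m):
            e = np.zeros(m)
            e[: k + 1] = 1.0
            out.append(self._estimate(f"lag0-{k} cumulative", e))
        return out

    def summary(self) -> str:
        lines = [
            f"County {self.model.county_id} ({self.model.zone or 'unstratified'}), "
            f"cause={self.model.cause}",
            f"n_obs={self.nobs}  dispersion={self.dispersion:.3f}  "
            f"deviance={self.qpfit.deviance:.1f}",
            "",
            f"{'effect':<22}{'beta/10ug':>12}{'se':>10}{'pct change':>12}",
        ]
        for e in self.effects():
            pct = (np.exp(e.beta) - 1) * 100
            lines.append(f"{e.lag:<22}{e.beta:>12.5f}{e.se:>10.5f}{pct:>11.2f}%")
        return "\n".join(lines)


def fit_county_dlm(
    panel: pd.DataFrame,
    county_id: str = "county",
    cause: str = "cvd",
    zone: str | None = None,
    confounders: ConfounderConfig = ConfounderConfig(),
    copollutant: str | None = None,
    max_lag: int = 4,
) -> list[EffectEstimate]:
    """Fit the joint distributed-lag model and return all effect estimates
    (single-day lags 0..max_lag and cumulative 0..k for k=1..max_lag)."""
    model = CountyNO2Model(
        panel,
        county_id=county_id,
        cause=cause,
        zone=zone,
        lag=LagSpec("single", max_lag),
        confounders=confounders,
        copollutant=copollutant,
    )
    return model.fit().effects()


@dataclass
class NonlinearNO2Fit:
    """Spline coefficient block for the lag-0 concentration-response curve."""

    county_id: str
    coef: np.ndarray            # (df,) exposure-basis coefficients
    cov: np.ndarray             # (df, df)
    knots: tuple[float, ...]
    boundary: tuple[float, float]
    basis: object               # SplineBasis, for evaluation on a grid

    def curve(self, grid: np.ndarray, ref: float) -> np.ndarray:
        b = self.basis.evaluate(np.asarray(grid, float)) - self.basis.evaluate(
            np.array([ref])
        )
        return b @ self.coef


def fit_nonlinear_no2(
    panel: pd.DataFrame,
    county_id: str = "county",
    cause: str = "cvd",
    zone: str | None = None,
    knots: tuple[float, float] = (20.0, 40.0),
    boundary: tuple[float, float] | None = None,
    confounders: ConfounderConfig = ConfounderConfig(),
) -> NonlinearNO2Fit:
    """Fit the lag-0 model with NO2 entered as a natural spline.

    The interior knots default to 20 and 40 ug/m3. ``boundary`` must be
    shared across counties when the fits are destined for curve pooling;
    it defaults to the county's own NO2 range.

    Raises ``ValueError`` when the county's NO2 range does not span the
    interior knots.
    """
    no2 = panel["no2"].to_numpy(dtype=float)
    if no2.min() >= min(knots) or no2.max() <= max(knots):
        raise ValueError(
            f"county {county_id}: NO2 range ({no2.min():.1f}, {no2.max():.1f}) "
            f"does not span knots {knots}"
        )
    df = len(knots) + 1
    sb = ns_basis(no2, df=df, knots=knots, boundary=boundary)

    base = CountyNO2Model(
        panel,
        county_id=county_id,
        cause=cause,
        zone=zone,
        lag=LagSpec("single", 0),
        confounders=confounders,
    )
    y, X, _ = base._build_design()
    X = X.drop(columns=["lag0"])
    keep_idx = X.index
    for j in range(df):
        X[f"no2_ns{j + 1}"] = sb.matrix[keep_idx, j]
    qp = fit_quasi_poisson(y, X)
    cols = [f"no2_ns{j + 1}" for j in range(df)]
    return NonlinearNO2Fit(
        county_id=county_id,
        coef=qp.params[cols].to_numpy(),
        cov=qp.cov.loc[cols, cols].to_numpy(),
        knots=tuple(float(k) for k in knots),
        boundary=sb.boundary,
        basis=sb,
    )
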