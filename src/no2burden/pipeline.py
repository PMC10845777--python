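"""End-to-end orchestration: load/validate inputs, fit every county, pool
by stratum, test urban-rural contrasts, and compute guideline burdens.

Outputs are plain CSVs plus a JSON manifest recording a hash of the
configuration and the package versions used, so a run is auditable and
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import scenario_report
from .county import ConfounderConfig, CountyExcludedError, fit_county_dlm
from .meta import PooledEffect, pool_random_effects, urban_rural_test

log = logging.getLogger("no2burden")

__all__ = ["PipelineConfig", "ValidationIssue", "validate_panel", "run_pipeline"]

PANEL_COLUMNS = [
    "county_id", "date", "cause", "admissions", "no2",
    "copollutant", "temp", "rh", "holiday",
]
COUNTY_COLUMNS = [
    "county_id", "zone", "avg_expense", "avg_stay", "gdp_per_capita", "beds_per_1000",
]
ANNUAL_COLUMNS = ["county_id", "year", "n_admissions", "no2_annual_mean"]


@dataclass
class PipelineConfig:
    """Run configuration; defaults mirror the main-model adjustment set
    (calendar spline 7 df/year, temperature 6 df, humidity 3 df, 3-day
    moving averages, lags 0-4)."""

    panel: str = "panel.csv"
    counties: str = "counties.csv"
    annual: str = "annual.csv"
    causes: tuple[str, ...] = ("cvd",)
    max_lag: int = 4
    time_df_per_year: float = 7.0
    temp_df: int = 6
    rh_df: int = 3
    ma_window: int = 3
    strata_column: str = "zone"
    aqgs: tuple[float, ...] = (10.0, 40.0)
    copollutant: str | None = None
    age_group: str | None = None
    pooling_method: str = "reml"
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("causes", "aqgs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def confounders(self) -> ConfounderConfig:
        return ConfounderConfig(
            time_df_per_year=self.time_df_per_year,
            temp_df=self.temp_df,
            rh_df=self.rh_df,
            ma_window=self.ma_window,
        )

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationIssue:
    file: str
    column: str | None
    row: int | None
    message: str


def validate_panel(path) -> list[ValidationIssue]:
    """Schema and plausibility checks on a panel CSV.

    Verifies column presence, nonnegative counts, concentration range
    (0-1000 ug/m3) and per-county date continuity; returns a
    machine-readable issue list (empty for a well-formed panel).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"panel file not found: {path}")
    issues: list[ValidationIssue] = []
    df = pd.read_csv(path, parse_dates=["date"])
    for col in PANEL_COLUMNS:
        if col not in df.columns:
            issues.append(ValidationIssue(str(path), col, None, "missing column"))
    if issues:
        return issues
    for i in df.index[df["admissions"] < 0]:
        issues.append(
            ValidationIssue(str(path), "admissions", int(i), "negative admission count")
        )
    for col in ("no2", "copollutant"):
        bad = df.index[(df[col] <= 0) | (df[col] > 1000)]
        for i in bad:
            issues.append(
                ValidationIssue(str(path), col, int(i), "implausible concentration")
            )
    for cid, g in df.groupby("county_id"):
        d = pd.DatetimeIndex(g["date"])
        gaps = np.diff(d.values).astype("timedelta64[D]").astype(int)
        if len(gaps) and not np.all(gaps == 1):
            where = int(np.argmax(gaps != 1))
            issues.append(
                ValidationIssue(
                    str(path), "date", int(g.index[where + 1]),
                    f"non-consecutive dates for county {cid}",
                )
            )
    return issues


def _stage1(panel, counties, cfg) -> tuple[list, list[str]]:
    zone_of = counties.set_index("county_id")["zone"].to_dict()
    estimates, excluded = [], []
    for cause in cfg.causes:
        sub_cause = panel[panel["cause"] == cause]
        if cfg.age_group is not None and "age_group" in panel.columns:
            sub_cause = sub_cause[sub_cause["age_group"] == cfg.age_group]
            sub_cause = (
                sub_cause.groupby(["county_id", "date"], as_index=False)
                .agg({**{c: "first" for c in ("cause", "no2", "copollutant",
                                               "temp", "rh", "holiday")},
                      "admissions": "sum"})
            )
        for cid, g in sub_cause.groupby("county_id"):
            g = g.sort_values("date").reset_index(drop=True)
            try:
                estimates.extend(
                    fit_county_dlm(
                        g, county_id=cid, cause=cause, zone=zone_of.get(cid),
                        confounders=cfg.confounders(),
                        copollutant=cfg.copollutant, max_lag=cfg.max_lag,
                    )
                )
            except CountyExcludedError as exc:
                excluded.append(str(exc))
                log.warning("excluded: %s", exc)
    return estimates, excluded


def _stage2(estimates, cfg):
    pooled, tests = [], []
    keyed = {}
    causes = sorted({e.cause for e in estimates})
    lags = sorted({e.lag for e in estimates})
    for cause in causes:
        for lag in lags:
            cell = [e for e in estimates if e.cause == cause and e.lag == lag]
            if not cell:
                continue
            strata = {"overall": cell}
            for z in ("urban", "rural"):
                zcell = [e for e in cell if e.zone == z]
                if zcell:
                    strata[z] = zcell
            for name, es in strata.items():
                p = pool_random_effects(es, stratum=name, method=cfg.pooling_method)
                pooled.append(p)
                keyed[(name, cause, lag)] = p
            if ("urban", cause, lag) in keyed and ("rural", cause, lag) in keyed:
                tests.append(
                    urban_rural_test(keyed[("urban", cause, lag)],
                                     keyed[("rural", cause, lag)])
                )
    return pooled, tests, keyed


def run_pipeline(cfg: PipelineConfig, data=None) -> dict:
    """Run the three stages and write the report bundle to ``cfg.out_dir``.

    ``data`` may be a :class:`~no2burden.simulate.SyntheticPanel` (or any
    object with ``panel``/``counties``/``annual`` frames) to bypass file
    loading; otherwise the configured CSVs are read and validated.

    Returns a dict with the in-memory estimates, pooled effects, difference
    tests, burden table and the manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        issues = validate_panel(cfg.panel)
        if issues:
            raise ValueError(
                "panel validation failed: "
                + "; ".join(f"{i.column}@{i.row}: {i.message}" for i in issues[:10])
            )
        panel = pd.read_csv(cfg.panel, parse_dates=["date"])
        counties = pd.read_csv(cfg.counties)
        annual = pd.read_csv(cfg.annual)
    else:
        panel, counties, annual = data.panel, data.counties, data.annual
    missing = [c for c in COUNTY_COLUMNS if c not in counties.columns]
    if missing:
        raise ValueError(f"county metadata missing columns {missing}")

    log.info("stage 1: fitting %d counties", panel["county_id"].nunique())
    estimates, excluded = _stage1(panel, counties, cfg)
    if not estimates:
        raise RuntimeError("stage 1 produced no estimates")
    est_df = pd.DataFrame(
        [
            {"county_id": e.county_id, "zone": e.zone, "cause": e.cause,
             "lag": e.lag, "beta_per10": e.beta, "se": e.se}
            for e in estimates
        ]
    ).sort_values(["cause", "lag", "county_id"], kind="stable")

    log.info("stage 2: pooling")
    pooled, tests, keyed = _stage2(estimates, cfg)
    pooled_df = pd.DataFrame(
        [
            {"stratum": p.stratum, "cause": p.cause, "lag": p.lag,
             "pct": p.pct[0], "lo": p.pct[1], "hi": p.pct[2],
             "tau2": p.tau2, "I2": p.i2, "k": p.k}
            for p in pooled
        ]
    ).sort_values(["cause", "lag", "stratum"], kind="stable")
    tests_df = pd.DataFrame(
        [
            {"cause": t.cause, "lag": t.lag, "z": t.z, "p": t.p}
            for t in tests
        ]
    )

    log.info("stage 3: burden scenarios %s", cfg.aqgs)
    exposures = annual.merge(
        counties[["county_id", "zone"]], on="county_id", how="left"
    )
    cumulative_label = f"lag0-{cfg.max_lag} cumulative" if cfg.max_lag > 0 else "lag0"
    effects_for_burden = {
        (stratum, cause): keyed[(stratum, cause, "lag0")]
        for stratum in ("overall", "urban", "rural")
        for cause in cfg.causes
        if (stratum, cause, "lag0") in keyed
    }
    burden_df = scenario_report(
        effects_for_burden, exposures, counties, aqgs=cfg.aqgs
    )

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.content_hash(),
        "n_counties_fit": int(est_df["county_id"].nunique()),
        "excluded": excluded,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    est_df.to_csv(out / "estimates.csv", index=False)
    pooled_df.to_csv(out / "pooled.csv", index=False)
    tests_df.to_csv(out / "difference_tests.csv", index=False)
    burden_df.to_csv(out / "burden.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "estimates": estimates,
        "pooled": keyed,
        "tests": tests,
        "burden": burden_df,
        "manifest": manifest,
        "excluded": excluded,
        "cumulative_label": cumulative_label,
    }
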