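"""Explanatory cohort analyses: health-service utilization contrasts and
urban/rural Kaplan-Meier survival with a log-rank test.

The survival machinery wraps lifelines; the utilization table is plain
count/quantile arithmetic on admission records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["utilization_table", "km_curve", "log_rank_test"]

FACILITY_LEVELS = ("primary", "secondary", "tertiary")


def utilization_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-zone admission counts and shares by facility level, with median
    (Q1, Q3) expense summaries.

    ``records`` needs columns ``zone``, ``facility_level``, ``expense``
    (thousand CNY). Returns one row per (zone, facility level) plus a
    ``total`` row per zone; shares are percentages of the zone total.
    """
    if len(records) == 0:
        raise ValueError("no admission records")
    bad = set(records["facility_level"]) - set(FACILITY_LEVELS)
    if bad:
        raise ValueError(f"unknown facility levels {sorted(bad)}")
    rows = []
    for zone, zdf in records.groupby("zone"):
        zone_n = len(zdf)
        for level in ("total",) + FACILITY_LEVELS:
            sub = zdf if level == "total" else zdf[zdf["facility_level"] == level]
            q1, med, q3 = (
                np.percentile(sub["expense"], [25, 50, 75])
                if len(sub)
                else (np.nan,) * 3
            )
            rows.append(
                {
                    "zone": zone,
                    "facility_level": level,
                    "n": len(sub),
                    "pct": 100.0 * len(sub) / zone_n,
                    "expense_median": med,
                    "expense_q1": q1,
                    "expense_q3": q3,
                }
            )
    return pd.DataFrame(rows)


def km_curve(records: pd.DataFrame, by: str = "zone") -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    ``records`` needs ``time`` (> 0) and ``event`` (1 = death) columns.
    Ties between events and censorings at the same time follow the standard
    convention (events first). Returns, per group, a step-function frame
    with columns ``time`` and ``survival`` starting at S(0) = 1.
    """
    if (records["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if int(records["event"].sum()) == 0 and records["time"].nunique() == 1:
        raise ValueError("degenerate input: all times identical with zero events")
    out = {}
    for group, gdf in records.groupby(by):
        kmf = KaplanMeierFitter()
        kmf.fit(gdf["time"], event_observed=gdf["event"])
        sf = kmf.survival_function_
        out[group] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out


def log_rank_test(records: pd.DataFrame, by: str = "zone") -> tuple[float, float]:
    """Unweighted log-rank test between two groups; returns (chi2, p)."""
    groups = records[by].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    if int(records["event"].sum()) == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(records["time"], records[by], records["event"])
    return float(res.test_statistic), float(res.p_value)
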