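"""Stage 3: attributable admissions, hospital days and expenses under
counterfactual air-quality-guideline NO2 levels.

For each county-year the relative risk of the observed annual mean D
against the guideline AQG is RR = exp(beta x max(D - AQG, 0) / 10); the
attributable number of admissions is N x (RR - 1)/RR, summed over
county-years. Hospital-day and expense burdens scale each county's
attributable admissions by its mean length of stay and mean expense per
admission. Attributable fractions divide by the stratum-wide outcome total.
Intervals plug the pooled beta's CI endpoints through the same formulas
(monotone in beta, so endpoints stay ordered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BurdenEstimate",
    "rr_at_concentration",
    "attributable_fraction",
    "attributable_admissions",
    "attributable_days_expenses",
    "scenario_report",
]


@dataclass
class BurdenEstimate:
    stratum: str
    cause: str
    outcome: str                # admissions | days | expenses
    aqg: float                  # ug/m3
    an: float
    an_lo: float
    an_hi: float
    af: float                   # percent
    af_lo: float
    af_hi: float

    def rounded(self) -> dict:
        """Reporting precision: AN to the nearest integer, AF to 2 dp."""
        return {
            "stratum": self.stratum, "cause": self.cause,
            "outcome": self.outcome, "aqg": self.aqg,
            "an": round(self.an), "an_lo": round(self.an_lo),
            "an_hi": round(self.an_hi),
            "af": round(self.af, 2), "af_lo": round(self.af_lo, 2),
            "af_hi": round(self.af_hi, 2),
        }


def rr_at_concentration(beta_per10: float, d, aqg: float):
    """RR of annual mean concentration ``d`` vs the guideline ``aqg``:
    exp(beta x max(d - aqg, 0) / 10). Counties already meeting the
    guideline contribute RR = 1 (no negative burden)."""
    if aqg <= 0:
        raise ValueError(f"AQG must be positive, got {aqg}")
    excess = np.maximum(np.asarray(d, dtype=float) - aqg, 0.0)
    return np.exp(beta_per10 * excess / 10.0)


def attributable_fraction(an: float, total: float) -> float:
    """AF in percent: 100 x AN / stratum outcome total."""
    if total <= 0:
        raise ValueError(f"outcome total must be positive, got {total}")
    return 100.0 * an / total


def _an_by_county(beta: float, exposures: pd.DataFrame, aqg: float) -> pd.Series:
    rr = rr_at_concentration(beta, exposures["no2_annual_mean"], aqg)
    an_ic = exposures["n_admissions"].to_numpy(dtype=float) * (rr - 1.0) / rr
    return pd.Series(an_ic, index=exposures.index).groupby(
        exposures["county_id"]
    ).sum()


def attributable_admissions(
    pooled,
    exposures: pd.DataFrame,
    aqg: float,
    stratum: str = "overall",
    denominator: str = "stratum",
) -> tuple[BurdenEstimate, pd.DataFrame]:
    """Attributable number and fraction of admissions for one stratum.

    Parameters
    ----------
    pooled : object with ``beta``, ``ci`` (log-RR per 10 ug/m3), ``cause``.
    exposures : county-year table with columns ``county_id``,
        ``n_admissions``, ``no2_annual_mean``.
    denominator : ``"stratum"`` divides by the total admissions of all
        counties in the stratum; ``"exceeding"`` restricts the denominator
        to county-years above the guideline.

    Returns the stratum :class:`BurdenEstimate` and a per-county frame with
    columns ``an``, ``an_lo``, ``an_hi`` (needed for day/expense scaling).
    """
    if len(exposures) == 0:
        raise ValueError("empty exposure table")
    if denominator not in {"stratum", "exceeding"}:
        raise ValueError(f"unknown denominator {denominator!r}")
    lo_b, hi_b = pooled.ci
    per_county = pd.DataFrame(
        {
            "an": _an_by_county(pooled.beta, exposures, aqg),
            "an_lo": _an_by_county(lo_b, exposures, aqg),
            "an_hi": _an_by_county(hi_b, exposures, aqg),
        }
    )
    if denominator == "stratum":
        total = float(exposures["n_admissions"].sum())
    else:
        mask = exposures["no2_annual_mean"] > aqg
        total = float(exposures.loc[mask, "n_admissions"].sum())
    an, an_lo, an_hi = (float(per_county[c].sum()) for c in ("an", "an_lo", "an_hi"))
    est = BurdenEstimate(
        stratum=stratum, cause=pooled.cause, outcome="admissions", aqg=aqg,
        an=an, an_lo=an_lo, an_hi=an_hi,
        af=attributable_fraction(an, total),
        af_lo=attributable_fraction(an_lo, total),
        af_hi=attributable_fraction(an_hi, total),
    )
    return est, per_county


def attributable_days_expenses(
    an_by_county: pd.DataFrame,
    costs: pd.DataFrame,
    total_days: float,
    total_expenses: float,
    stratum: str = "overall",
    cause: str = "cvd",
    aqg: float = 10.0,
) -> tuple[BurdenEstimate, BurdenEstimate]:
    """Scale per-county attributable admissions into hospital days and
    expenses: days_c = ADc x AN_c, expenses_c = AEc x AN_c.

    ``costs`` must carry ``county_id``, ``avg_stay`` (days) and
    ``avg_expense`` (thousand CNY); a county with nonzero AN but no cost
    record is an error naming the county.
    """
    costs = costs.set_index("county_id") if "county_id" in costs.columns else costs
    missing = [
        c for c in an_by_county.index
        if c not in costs.index and abs(an_by_county.loc[c, "an"]) > 0
    ]
    if missing:
        raise KeyError(f"no cost record for counties {missing}")
    aligned = costs.reindex(an_by_county.index).fillna(0.0)
    out = []
    for outcome, col, total in (
        ("days", "avg_stay", total_days),
        ("expenses", "avg_expense", total_expenses),
    ):
        scale = aligned[col].to_numpy(dtype=float)
        vals = {
            key: float((an_by_county[key].to_numpy() * scale).sum())
            for key in ("an", "an_lo", "an_hi")
        }
        out.append(
            BurdenEstimate(
                stratum=stratum, cause=cause, outcome=outcome, aqg=aqg,
                an=vals["an"], an_lo=vals["an_lo"], an_hi=vals["an_hi"],
                af=attributable_fraction(vals["an"], total),
                af_lo=attributable_fraction(vals["an_lo"], total),
                af_hi=attributable_fraction(vals["an_hi"], total),
            )
        )
    return out[0], out[1]


def scenario_report(
    pooled_effects: dict,
    exposures: pd.DataFrame,
    costs: pd.DataFrame,
    aqgs=(10.0, 40.0),
    denominator: str = "stratum",
) -> pd.DataFrame:
    """Burden table across guideline scenarios.

    ``pooled_effects`` maps (stratum, cause) to a pooled effect;
    ``exposures`` carries ``zone`` alongside the county-year columns so each
    stratum's rows can be selected (stratum ``"overall"`` uses all rows).
    Outcome totals for days/expenses are reconstructed from the cost table
    (total = sum over counties of N_c x ADc or N_c x AEc).

    Returns one row per (stratum, cause, outcome, AQG).
    """
    rows = []
    costs_idx = costs.set_index("county_id") if "county_id" in costs.columns else costs
    for (stratum, cause), pooled in pooled_effects.items():
        sub = exposures if stratum == "overall" else exposures[exposures["zone"] == stratum]
        if len(sub) == 0:
            raise ValueError(f"no exposure rows for stratum {stratum!r}")
        n_by_county = sub.groupby("county_id")["n_admissions"].sum()
        aligned = costs_idx.reindex(n_by_county.index)
        total_days = float((n_by_county * aligned["avg_stay"]).sum())
        total_exp = float((n_by_county * aligned["avg_expense"]).sum())
        for aqg in aqgs:
            adm, per_county = attributable_admissions(
                pooled, sub, aqg, stratum=stratum, denominator=denominator
            )
            days, exp = attributable_days_expenses(
                per_county, costs, total_days, total_exp,
                stratum=stratum, cause=cause, aqg=aqg,
            )
            rows.extend([adm.rounded(), days.rounded(), exp.rounded()])
    return pd.DataFrame(rows)
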