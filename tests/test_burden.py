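"""Stage-3 burden arithmetic against direct-summation oracles and its
analytic limits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from no2burden import (
    attributable_admissions,
    attributable_days_expenses,
    attributable_fraction,
    rr_at_concentration,
    scenario_report,
)
from no2burden.meta import PooledEffect


def _pooled(beta, se=0.002, cause="cvd"):
    return PooledEffect("overall", cause, "lag0", beta, se, 0.0, 0.0, 10)


@pytest.fixture()
def six_county_years():
    """Small exposure table: 3 counties x 2 years, one county compliant."""
    return pd.DataFrame(
        {
            "county_id": ["a", "a", "b", "b", "c", "c"],
            "year": [2015, 2016] * 3,
            "n_admissions": [1200, 1300, 800, 850, 2000, 2100],
            "no2_annual_mean": [35.0, 33.0, 42.0, 41.0, 9.0, 8.5],
        }
    )


class TestRelativeRisk:
    @pytest.mark.parametrize(
        "beta,d,aqg,expected",
        [
            (0.05, 10.0, 10.0, 1.0),               # at the guideline
            (0.0, 55.0, 10.0, 1.0),                # null effect
            (np.log(1.0142), 20.0, 10.0, 1.0142),  # one 10-unit excess
        ],
    )
    def test_closed_form_points(self, beta, d, aqg, expected):
        assert rr_at_concentration(beta, d, aqg) == pytest.approx(expected, abs=1e-12)

    def test_compliant_counties_clamped(self):
        rr = rr_at_concentration(0.05, np.array([5.0, 9.9, 10.0]), 10.0)
        assert np.all(rr == 1.0)

    def test_invalid_aqg(self):
        with pytest.raises(ValueError, match="AQG"):
            rr_at_concentration(0.01, 20.0, 0.0)


class TestAttributableAdmissions:
    def test_direct_summation_oracle(self, six_county_years):
        """Vectorized AN matches the per-row spreadsheet arithmetic."""
        beta = np.log(1.0142)
        pooled = _pooled(beta)
        est, per_county = attributable_admissions(pooled, six_county_years, aqg=10.0)
        an_manual = 0.0
        for _, row in six_county_years.iterrows():
            rr = np.exp(beta * max(row.no2_annual_mean - 10.0, 0.0) / 10.0)
            an_manual += row.n_admissions * (rr - 1.0) / rr
        assert est.an == pytest.approx(an_manual, abs=1e-9)
        assert est.af == pytest.approx(
            100.0 * an_manual / six_county_years.n_admissions.sum(), abs=1e-9
        )
        assert per_county.loc["c", "an"] == 0.0  # compliant county

    def test_all_at_guideline_zero_burden(self, six_county_years):
        exp = six_county_years.assign(no2_annual_mean=10.0)
        est, _ = attributable_admissions(_pooled(0.02), exp, aqg=10.0)
        assert est.an == 0.0 and est.af == 0.0

    def test_interval_ordering(self, six_county_years):
        est, _ = attributable_admissions(_pooled(0.014, 0.004), six_county_years, 10.0)
        assert est.an_lo <= est.an <= est.an_hi
        assert est.af_lo <= est.af <= est.af_hi

    def test_empty_exposures_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            attributable_admissions(_pooled(0.01), pd.DataFrame(columns=["county_id", "n_admissions", "no2_annual_mean"]), 10.0)

    @given(st.floats(0.5, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_af_invariant_to_count_rescaling(self, factor):
        exp = pd.DataFrame(
            {
                "county_id": ["a", "b"],
                "year": [2015, 2015],
                "n_admissions": [1000.0, 2000.0],
                "no2_annual_mean": [30.0, 45.0],
            }
        )
        base, _ = attributable_admissions(_pooled(0.014), exp, 10.0)
        scaled, _ = attributable_admissions(
            _pooled(0.014), exp.assign(n_admissions=exp.n_admissions * factor), 10.0
        )
        assert scaled.af == pytest.approx(base.af, rel=1e-12)

    def test_monotone_in_beta_and_concentration(self, six_county_years):
        an = [
            attributable_admissions(_pooled(b), six_county_years, 10.0)[0].an
            for b in (0.005, 0.010, 0.020)
        ]
        assert an[0] < an[1] < an[2]
        shifted = six_county_years.assign(
            no2_annual_mean=six_county_years.no2_annual_mean + 5.0
        )
        higher, _ = attributable_admissions(_pooled(0.01), shifted, 10.0)
        assert higher.an > attributable_admissions(_pooled(0.01), six_county_years, 10.0)[0].an


class TestDaysExpenses:
    def _costs(self):
        return pd.DataFrame(
            {
                "county_id": ["a", "b", "c"],
                "avg_expense": [10.0, 8.0, 6.0],
                "avg_stay": [15.0, 12.0, 9.0],
            }
        )

    def test_scaling_by_county_costs(self, six_county_years):
        pooled = _pooled(np.log(1.0142))
        _, per_county = attributable_admissions(pooled, six_county_years, 10.0)
        days, exp = attributable_days_expenses(
            per_county, self._costs(), total_days=50_000.0, total_expenses=40_000.0
        )
        manual_days = (
            per_county.loc["a", "an"] * 15.0 + per_county.loc["b", "an"] * 12.0
        )
        assert days.an == pytest.approx(manual_days, abs=1e-9)
        assert days.af == pytest.approx(100.0 * manual_days / 50_000.0, abs=1e-9)
        assert exp.outcome == "expenses"

    def test_zero_an_zero_burden(self, six_county_years):
        _, per_county = attributable_admissions(_pooled(0.0), six_county_years, 10.0)
        days, exp = attributable_days_expenses(
            per_county, self._costs(), 50_000.0, 40_000.0
        )
        assert days.an == 0.0 and exp.an == 0.0

    def test_missing_cost_record_names_county(self, six_county_years):
        costs = self._costs().iloc[:1]
        _, per_county = attributable_admissions(
            _pooled(np.log(1.0142)), six_county_years, 10.0
        )
        with pytest.raises(KeyError, match="b"):
            attributable_days_expenses(per_county, costs, 50_000.0, 40_000.0)


class TestScenarioReport:
    def test_guideline_monotonicity_and_clamping(self, six_county_years):
        exposures = six_county_years.assign(
            zone=["urban", "urban", "rural", "rural", "rural", "rural"]
        )
        costs = pd.DataFrame(
            {
                "county_id": ["a", "b", "c"],
                "avg_expense": [10.0, 8.0, 6.0],
                "avg_stay": [15.0, 12.0, 9.0],
            }
        )
        pooled = {("overall", "cvd"): _pooled(np.log(1.0142), 0.003)}
        report = scenario_report(pooled, exposures, costs, aqgs=(10.0, 40.0))
        for outcome in ("admissions", "days", "expenses"):
            sub = report[report.outcome == outcome].set_index("aqg")
            assert sub.loc[40.0, "an"] <= sub.loc[10.0, "an"]
        # every county-year below 40 except county b -> WHO-2005 burden from b only
        only_b = exposures[exposures.no2_annual_mean > 40.0]
        assert len(only_b) == 2

    def test_all_between_guidelines_zero_2005_burden(self):
        exposures = pd.DataFrame(
            {
                "county_id": ["a", "b"],
                "year": [2015, 2015],
                "n_admissions": [500, 700],
                "no2_annual_mean": [25.0, 35.0],
                "zone": ["urban", "rural"],
            }
        )
        costs = pd.DataFrame(
            {"county_id": ["a", "b"], "avg_expense": [9.0, 7.0], "avg_stay": [12.0, 9.0]}
        )
        report = scenario_report(
            {("overall", "cvd"): _pooled(0.02)}, exposures, costs, aqgs=(10.0, 40.0)
        )
        who2005 = report[report.aqg == 40.0]
        assert (who2005["an"] == 0).all() and (who2005["af"] == 0).all()


def test_attributable_fraction_identity():
    assert attributable_fraction(5447, 160652) == pytest.approx(3.39, abs=0.005)
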