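"""Stage-2 pooling: closed-form oracles, transform identities, the
urban-rural contrast, meta-regression and curve pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from no2burden import (
    RandomEffectsMeta,
    SimulationConfig,
    ci_to_log_scale,
    fit_nonlinear_no2,
    percentage_change,
    pool_curves,
    pool_random_effects,
    simulate_panel,
    urban_rural_test,
)
from no2burden.county import EffectEstimate
from no2burden.meta import MetaRegression, PooledEffect


def dl_oracle(y, v):
    """Hand-computed DerSimonian-Laird method of moments."""
    w = 1.0 / np.asarray(v)
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (np.asarray(y) - mu) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (len(y) - 1)) / c)
    w2 = 1.0 / (np.asarray(v) + tau2)
    return np.sum(w2 * y) / np.sum(w2), np.sqrt(1.0 / np.sum(w2)), tau2


def _ests(betas, ses, zone=None):
    return [
        EffectEstimate("c%d" % i, "cvd", "lag0", b, s, zone)
        for i, (b, s) in enumerate(zip(betas, ses))
    ]


class TestPooling:
    def test_identical_estimates_collapse(self):
        p = pool_random_effects(_ests([0.02] * 5, [0.004] * 5))
        assert p.beta == pytest.approx(0.02, abs=1e-12)
        assert p.tau2 == pytest.approx(0.0, abs=1e-10)
        assert p.i2 == 0.0

    def test_dl_matches_closed_form(self):
        y, v = [0.010, 0.020], [0.002**2, 0.002**2]
        res = RandomEffectsMeta(y, np.sqrt(v)).fit(method="dl")
        mu, se, tau2 = dl_oracle(y, v)
        assert res.beta == pytest.approx(mu, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.tau2 == pytest.approx(tau2, abs=1e-10)

    def test_dl_cross_checked_against_statsmodels(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.01, 0.01, 12)
        se = rng.uniform(0.003, 0.01, 12)
        ours = RandomEffectsMeta(y, se).fit(method="dl")
        ref = combine_effects(y, se**2, method_re="chi2")
        assert ours.tau2 == pytest.approx(float(ref.tau2), abs=1e-10)

    def test_fixed_effect_limit(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.01, 0.005, 8)
        se = rng.uniform(0.002, 0.02, 8)
        res = RandomEffectsMeta(y, se).fit(method="fixed")
        w = 1.0 / se**2
        assert res.beta == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-12)

    def test_reml_close_to_dl_when_homogeneous(self):
        """On tau2=0 truth with k=30, REML and DL pooled estimates agree to
        within 10% of the pooled SE."""
        rng = np.random.default_rng(9)
        se = np.full(30, 0.004)
        y = rng.normal(0.014, se)
        r = RandomEffectsMeta(y, se)
        reml, dl = r.fit("reml"), r.fit("dl")
        assert abs(reml.beta - dl.beta) < 0.1 * dl.se

    def test_single_estimate_degenerate(self):
        p = pool_random_effects(_ests([0.01], [0.002]))
        assert p.degenerate and p.tau2 == 0.0 and p.k == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_random_effects([])

    @given(
        st.lists(
            st.tuples(st.floats(-0.05, 0.05), st.floats(0.001, 0.02)),
            min_size=2, max_size=12,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_pooled_within_county_range(self, pairs):
        """Nonnegative inverse-variance weights keep the pooled estimate
        inside [min, max] of the county estimates."""
        betas = [p[0] for p in pairs]
        ses = [p[1] for p in pairs]
        pooled = RandomEffectsMeta(betas, ses).fit("reml")
        assert min(betas) - 1e-12 <= pooled.beta <= max(betas) + 1e-12


class TestTransforms:
    @pytest.mark.parametrize(
        "beta,expected", [(0.0, 0.0), (np.log(1.0142), 1.42), (-0.01, -0.995)]
    )
    def test_percentage_change_points(self, beta, expected):
        pct, lo, hi = percentage_change(beta, 0.004)
        assert pct == pytest.approx(expected, abs=0.01)
        assert lo < pct < hi

    def test_ci_to_log_scale_frozen_values(self):
        beta, se = ci_to_log_scale(0.0, -1.96, 1.96)
        assert beta == pytest.approx(0.0, abs=1e-15)
        # closed form: [log(1.0196) - log(0.9804)] / 3.92
        assert se == pytest.approx(0.0100013, abs=1e-6)
        beta_u, _ = ci_to_log_scale(1.51, 0.82, 2.21)
        assert beta_u == pytest.approx(0.014987, abs=1e-5)

    def test_round_trip(self):
        beta, se = ci_to_log_scale(*percentage_change(0.0132, 0.0041))
        assert beta == pytest.approx(0.0132, abs=1e-12)
        assert se == pytest.approx(0.0041, abs=1e-12)

    def test_non_nested_ci_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            ci_to_log_scale(1.0, 1.5, 2.0)


class TestUrbanRuralTest:
    def _pooled(self, beta, se, stratum, lag="lag0"):
        return PooledEffect(stratum, "cvd", lag, beta, se, 0.0, 0.0, 10)

    def test_identical_strata_z_zero(self):
        u = self._pooled(0.014, 0.004, "urban")
        r = self._pooled(0.014, 0.004, "rural")
        t = urban_rural_test(u, r)
        assert t.z == 0.0 and t.p == 1.0

    def test_mismatched_cells_rejected(self):
        u = self._pooled(0.01, 0.004, "urban", lag="lag0")
        r = self._pooled(0.01, 0.004, "rural", lag="lag1")
        with pytest.raises(ValueError, match="mismatched"):
            urban_rural_test(u, r)


class TestMetaRegression:
    def test_constant_moderator_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            MetaRegression(
                np.random.default_rng(0).normal(0, 1, 10),
                np.full(10, 0.1),
                pd.DataFrame({"gdp": np.ones(10)}),
            )

    def test_moderator_slope_recovery(self):
        rng = np.random.default_rng(13)
        k = 40
        gdp = rng.uniform(-1, 1, k)
        se = np.full(k, 0.003)
        y = 0.010 + 0.008 * gdp + rng.normal(0, se)
        res = MetaRegression(y, se, pd.DataFrame({"gdp": gdp})).fit()
        slope = res.table.loc["gdp"]
        assert abs(slope["coef"] - 0.008) < 2 * slope["se"]

    def test_null_moderator_leaves_heterogeneity(self):
        """An irrelevant moderator changes residual I2 little on average."""
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(30):
            k = 30
            se = np.full(k, 0.004)
            y = rng.normal(0.014, np.sqrt(se**2 + 0.003**2))
            unadj = RandomEffectsMeta(y, se).fit("reml").i2
            res = MetaRegression(
                y, se, pd.DataFrame({"noise": rng.normal(size=k)})
            ).fit()
            diffs.append(res.i2_residual - unadj)
        assert abs(np.mean(diffs)) < 10.0


class TestCurvePooling:
    def _fits(self, n_counties, pct, seed):
        cfg = SimulationConfig(
            n_urban_counties=max(n_counties // 2, 1),
            n_rural_counties=max(n_counties - n_counties // 2, 1),
            n_years=2, true_pct_per_10=pct,
            lag_weights=(1.0, 0, 0, 0, 0), seed=seed,
        )
        sim = simulate_panel(cfg)
        return [
            fit_nonlinear_no2(
                g.reset_index(drop=True), county_id=cid, boundary=(5.0, 90.0)
            )
            for cid, g in sim.panel.groupby("county_id")
        ]

    def test_single_county_passthrough(self):
        fits = self._fits(2, 1.42, 61)[:1]
        grid = np.linspace(20, 60, 9)
        pooled = pool_curves(fits, grid, ref=36.0)
        own = fits[0].curve(grid, ref=36.0)
        assert np.allclose(pooled["logrr"], own, atol=1e-10)

    def test_curve_zero_at_reference(self):
        fits = self._fits(4, 1.42, 62)
        pooled = pool_curves(fits, np.array([36.0, 40.0]), ref=36.0)
        assert pooled["logrr"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_truth_yields_increasing_curve(self):
        fits = self._fits(6, 3.0, 63)
        grid = np.linspace(20, 60, 15)
        pooled = pool_curves(fits, grid, ref=36.0)
        assert pooled["logrr"].iloc[-1] > pooled["logrr"].iloc[0]

    def test_basis_mismatch_rejected(self):
        fits = self._fits(2, 1.42, 64)
        other = self._fits(2, 1.42, 64)
        other[1].knots = (15.0, 45.0)
        with pytest.raises(ValueError, match="basis mismatch"):
            pool_curves([fits[0], other[1]], np.linspace(20, 60, 5), ref=36.0)
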