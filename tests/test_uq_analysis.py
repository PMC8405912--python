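import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytotea.assumptions import AssumptionSpec
from phytotea.uq_analysis import (
    assumption_quantile,
    compare_scenarios,
    contribution_to_variance,
    extremal_trials,
    qq_points,
    spider,
    tornado,
)


class TestCompareScenarios:
    def test_identical_samples(self, rng):
        x = rng.normal(size=100)
        res = compare_scenarios(x, x.copy())
        assert res.ks_statistic == 0.0
        assert res.t_statistic == 0.0

    def test_power_at_unit_separation(self):
        rng = np.random.default_rng(99)
        a = rng.normal(0, 1, 5000)
        b = rng.normal(1, 1, 5000)
        res = compare_scenarios(a, b)
        assert res.t_pvalue < 1e-10
        assert res.ks_pvalue < 1e-10

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_ks_matches_brute_force_ecdf_sup(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(5, 100), rng.integers(5, 100)
        a, b = rng.normal(size=na), rng.normal(0.3, 1.2, size=nb)
        res = compare_scenarios(a, b)
        grid = np.concatenate([a, b])
        ecdf_a = np.array([(a <= g).mean() for g in grid])
        ecdf_b = np.array([(b <= g).mean() for g in grid])
        assert res.ks_statistic == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_welch_t_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(5, 100), rng.integers(5, 100)
        a, b = rng.normal(size=na), rng.normal(0.5, 2.0, size=nb)
        res = compare_scenarios(a, b)
        t_brute = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / na + b.var(ddof=1) / nb)
        assert res.t_statistic == pytest.approx(t_brute, rel=1e-10)

    def test_zero_variance_flagged(self):
        res = compare_scenarios([1.0, 1.0, 1.0], [1.0, 1.0])
        assert not res.t_defined


class TestQQPoints:
    def test_standard_normal_slope_near_one(self):
        rng = np.random.default_rng(3)
        pts = qq_points(rng.normal(size=10_000))
        slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_constant_sample_zero_slope(self):
        pts = qq_points(np.full(50, 2.5))
        assert np.ptp(pts[:, 1]) == 0.0

    def test_monotone_pairs(self, rng):
        pts = qq_points(rng.normal(size=101))
        assert (np.diff(pts[:, 0]) > 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()


UNIT_SPECS = [
    AssumptionSpec("x1", "uniform", (0.0, 1.0)),
    AssumptionSpec("x2", "uniform", (0.0, 1.0)),
    AssumptionSpec("x3", "uniform", (0.0, 1.0)),
]
BASE = {"x1": 0.5, "x2": 0.5, "x3": 0.5}


class TestTornado:
    def test_identity_model_swing(self):
        res = tornado(lambda d: d["x1"], BASE, UNIT_SPECS[:1], percentiles=(0.1, 0.9))
        assert res.table.loc[0, "swing"] == pytest.approx(0.8)

    def test_inactive_parameter_ranked_last(self):
        res = tornado(lambda d: d["x1"] + 2 * d["x2"], BASE, UNIT_SPECS)
        assert res.table.iloc[-1]["parameter"] == "x3"
        assert res.table.iloc[-1]["swing"] == pytest.approx(0.0)

    def test_linear_model_swings_proportional_to_coefficients(self):
        res = tornado(lambda d: 3 * d["x1"] + 1 * d["x2"], BASE, UNIT_SPECS[:2])
        t = res.table.set_index("parameter")["swing"]
        assert t["x1"] / t["x2"] == pytest.approx(3.0)

    def test_swing_invariant_to_other_distributions(self):
        wide = [
            AssumptionSpec("x1", "uniform", (0.0, 1.0)),
            AssumptionSpec("x2", "uniform", (-100.0, 100.0)),
        ]
        r1 = tornado(lambda d: d["x1"], BASE, UNIT_SPECS[:2])
        r2 = tornado(lambda d: d["x1"], BASE, wide)
        s1 = r1.table.set_index("parameter").loc["x1", "swing"]
        s2 = r2.table.set_index("parameter").loc["x1", "swing"]
        assert s1 == pytest.approx(s2)

    def test_model_failure_flagged(self):
        def bad(d):
            if d["x1"] > 0.8:
                raise RuntimeError("boom")
            return d["x1"]

        res = tornado(bad, BASE, UNIT_SPECS[:1])
        assert res.failures and res.failures[0][0] == "x1"


class TestSpider:
    def test_curves_intersect_at_base_percentile(self):
        # with every input at its median, the 0.5 grid point is the base point
        model = lambda d: d["x1"] + d["x2"] + d["x3"]
        res = spider(model, BASE, UNIT_SPECS, grid=(0.25, 0.5, 0.75))
        at_base = res.curves.loc[0.5]
        assert np.allclose(at_base, at_base.iloc[0])

    def test_linear_model_straight_lines(self):
        res = spider(lambda d: 2 * d["x1"], BASE, UNIT_SPECS[:1], grid=(0.1, 0.3, 0.5, 0.7, 0.9))
        vals = res.curves["x1"].to_numpy()
        diffs = np.diff(vals)
        assert np.allclose(diffs, diffs[0])

    def test_inactive_parameter_flat(self):
        res = spider(lambda d: d["x1"], BASE, UNIT_SPECS[:2], grid=(0.2, 0.5, 0.8))
        assert np.ptp(res.curves["x2"].to_numpy()) == 0.0


class TestContributionToVariance:
    def test_single_driver_gets_all_variance(self, rng):
        x = pd.DataFrame({"x1": rng.uniform(size=500)})
        res = contribution_to_variance(x, x["x1"].to_numpy())
        assert res.shares["x1"] == pytest.approx(100.0)

    def test_equal_drivers_split_evenly(self):
        rng = np.random.default_rng(7)
        n = 20_000
        x = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        res = contribution_to_variance(x, (x["x1"] + x["x2"]).to_numpy())
        assert res.shares["x1"] == pytest.approx(50.0, abs=3.0)
        assert res.shares["x2"] == pytest.approx(50.0, abs=3.0)

    def test_stronger_driver_ranks_higher(self):
        rng = np.random.default_rng(8)
        n = 5000
        x = pd.DataFrame({"x1": rng.uniform(size=n), "x2": rng.uniform(size=n)})
        res = contribution_to_variance(x, (2 * x["x1"] + x["x2"]).to_numpy())
        assert res.shares["x1"] > res.shares["x2"] > 0

    def test_negative_driver_gets_signed_share(self):
        rng = np.random.default_rng(9)
        n = 2000
        x = pd.DataFrame({"x1": rng.uniform(size=n), "x2": rng.uniform(size=n)})
        res = contribution_to_variance(x, (x["x1"] - 2 * x["x2"]).to_numpy())
        assert res.shares["x2"] < 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_absolute_shares_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        x = pd.DataFrame(rng.uniform(size=(n, 4)), columns=list("abcd"))
        y = x @ rng.normal(size=4) + 0.1 * rng.normal(size=n)
        res = contribution_to_variance(x, y.to_numpy())
        assert res.shares.abs().sum() == pytest.approx(100.0, abs=0.1)


class TestExtremalTrials:
    def test_examples(self):
        df = pd.DataFrame({"trial": [0, 1, 2], "irr": [1.0, 2.0, 3.0]})
        lo, mid, hi = extremal_trials(df, "irr")
        assert (lo["irr"], mid["irr"], hi["irr"]) == (1.0, 2.0, 3.0)

    def test_duplicate_minimum_takes_first(self):
        df = pd.DataFrame({"trial": [0, 1, 2], "irr": [1.0, 1.0, 3.0]})
        lo, _, _ = extremal_trials(df, "irr")
        assert lo["trial"] == 0

    def test_nearest_to_mean_rule(self):
        df = pd.DataFrame({"trial": [0, 1, 2, 3], "irr": [1.0, 2.0, 3.0, 3.6]})
        _, mid, _ = extremal_trials(df, "irr")  # mean = 2.4
        assert mid["irr"] == 2.0

    def test_nan_forecasts_ignored(self):
        df = pd.DataFrame({"trial": [0, 1, 2], "irr": [np.nan, 2.0, 5.0]})
        lo, _, hi = extremal_trials(df, "irr")
        assert lo["irr"] == 2.0 and hi["irr"] == 5.0


class TestAssumptionQuantile:
    def test_respects_truncation(self):
        spec = AssumptionSpec("x", "logistic", (1.5, 0.3), truncation=(1.0, 2.0))
        assert assumption_quantile(spec, 0.001) >= 1.0
        assert assumption_quantile(spec, 0.999) <= 2.0
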