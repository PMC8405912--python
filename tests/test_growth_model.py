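import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytotea.growth_model import (
    ChamberDataset,
    GrowthModelParams,
    InvalidDesignError,
    PUBLISHED_TOBACCO_PARAMS,
    fit_growth_params,
    growth_rate,
    pooled_rmse,
    r_squared,
    read_chamber_csv,
    rmse,
    simulate_trajectory,
    step_dry_weight,
    weighted_day_temperature,
    write_chamber_csv,
)
from phytotea.synthetic_data import SyntheticExperimentDesign, synth_chamber_data


class TestWeightedDayTemperature:
    @pytest.mark.parametrize(
        "high, low, h_high, h_low, expected",
        [
            (300.0, 300.0, 9, 15, 300.0),  # identical temperatures
            (303.15, 293.15, 9, 15, 296.9),  # 9/24*303.15 + 15/24*293.15
            (300.0, 290.0, 12, 12, 295.0),  # symmetric split
        ],
    )
    def test_values(self, high, low, h_high, h_low, expected):
        assert weighted_day_temperature(high, low, h_high, h_low) == pytest.approx(expected)

    def test_bad_hour_split_rejected(self):
        with pytest.raises(InvalidDesignError):
            weighted_day_temperature(300.0, 290.0, 9, 14)


class TestGrowthRate:
    def test_zero_preexponential_gives_zero_rate(self):
        params = GrowthModelParams(A=0.0, k=1000.0, S=5.0, H=20000.0)
        assert growth_rate(300.0, params) == 0.0

    def test_closed_form_oracle(self):
        # independent single-line arithmetic evaluation of the rate law
        p = PUBLISHED_TOBACCO_PARAMS
        T = 300.0
        expected = p.A * T * math.exp(-p.k / T) / (1.0 + math.exp(p.S - p.H / T))
        assert growth_rate(T, p) == pytest.approx(expected, rel=1e-14)

    def test_arrhenius_limit_when_inactivation_negligible(self):
        # S - H/T << 0 makes the denominator -> 1
        p = GrowthModelParams(A=0.5, k=2000.0, S=5.0, H=30000.0)
        T = np.linspace(280.0, 310.0, 50)
        assert np.allclose(growth_rate(T, p), p.A * T * np.exp(-p.k / T), rtol=1e-10)

    def test_continuity(self):
        p = PUBLISHED_TOBACCO_PARAMS
        T = np.linspace(273.0, 320.0, 200)
        eps = 1e-7
        delta = np.abs(growth_rate(T + eps, p) - growth_rate(T, p))
        assert delta.max() < 1e-4

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(-1.0, PUBLISHED_TOBACCO_PARAMS)


class TestStepAndTrajectory:
    def test_single_step_formula(self):
        # with r forced to 0.1/day: 0.5 -> 0.55
        p = GrowthModelParams(A=1.0, k=1.0, S=0.0, H=1.0)
        T = 300.0
        r = growth_rate(T, p)
        w1 = step_dry_weight(0.5, T, 1.0, p)
        assert w1 == pytest.approx(0.5 * (1 + r))
        assert step_dry_weight(0.5, T, 1.0, GrowthModelParams(0.0, 1.0, 0.0, 1.0)) == 0.5

    def test_compounding_closed_form(self, true_params):
        T, n = 297.0, 27
        r = growth_rate(T, true_params)
        traj = simulate_trajectory(np.full(n, T), 0.5, true_params, dt=1.0)
        assert traj[0] == 0.5
        assert traj[-1] == pytest.approx(0.5 * (1 + r) ** n, rel=1e-12)
        assert np.all(np.diff(traj) > 0)

    def test_hourly_vs_daily_step_discrepancy_small(self, true_params):
        # hourly and daily stepping agree only in the dt -> 0 limit; over one
        # day with r*dt << 1 the discrepancy stays below 1%
        T = 297.0
        daily1 = simulate_trajectory([T], 0.5, true_params, dt=1.0)[-1]
        hourly1 = simulate_trajectory(np.full(24, T), 0.5, true_params, dt=1 / 24)[-1]
        assert abs(hourly1 - daily1) / daily1 < 0.01
        # the per-day bias compounds multiplicatively over a 27-day window
        daily27 = simulate_trajectory(np.full(27, T), 0.5, true_params, dt=1.0)[-1]
        hourly27 = simulate_trajectory(np.full(27 * 24, T), 0.5, true_params, dt=1 / 24)[-1]
        assert hourly27 / daily27 == pytest.approx((hourly1 / daily1) ** 27, rel=1e-9)

    def test_zero_length_horizon(self, true_params):
        assert simulate_trajectory([], 0.5, true_params, dt=1.0).tolist() == [0.5]

    def test_27_day_hourly_closed_form(self, true_params):
        r = growth_rate(295.0, true_params)
        out = simulate_trajectory(np.full(27 * 24, 295.0), 0.5, true_params, dt=1 / 24)
        assert out[-1] == pytest.approx(0.5 * (1 + r / 24) ** (27 * 24), rel=1e-12)


class TestErrorMetrics:
    def test_rmse_examples(self):
        assert rmse([1, 2], [1, 2]) == 0.0
        assert rmse([0, 0], [3, 4]) == pytest.approx(math.sqrt((9 + 16) / 2))

    def test_r_squared_examples(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
        obs = [1.0, 2.0, 3.0]
        assert r_squared([2.0, 2.0, 2.0], obs) == pytest.approx(0.0)
        assert r_squared([0.0, 0.0], [-1.0, 1.0]) == pytest.approx(0.0)

    def test_r_squared_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [3.0, 3.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_brute_force_equivalence(self, seed):
        # oracle: formulas written out longhand on random vectors
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 100)
        pred, obs = rng.normal(size=n), rng.normal(size=n)
        brute_rmse = math.sqrt(sum((p - o) ** 2 for p, o in zip(pred, obs)) / n)
        assert rmse(pred, obs) == pytest.approx(brute_rmse, rel=1e-12)
        o_avg = sum(obs) / n
        brute_r2 = 1 - sum((p - o) ** 2 for p, o in zip(pred, obs)) / sum(
            (o - o_avg) ** 2 for o in obs
        )
        assert r_squared(pred, obs) == pytest.approx(brute_r2, rel=1e-9, abs=1e-9)

    def test_rmse_permutation_invariance(self, rng):
        pred, obs = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        assert rmse(pred, obs) == pytest.approx(rmse(pred[perm], obs[perm]))


class TestFitGrowthParams:
    def test_noise_free_self_consistency(self, clean_chambers, true_params):
        res = fit_growth_params(clean_chambers, init=true_params)
        assert res.rmse < 1e-6
        assert res.r2 == pytest.approx(1.0)

    def test_noise_free_recovery_from_perturbed_init(self, clean_chambers, true_params):
        init = GrowthModelParams(
            A=true_params.A * 1.2,
            k=true_params.k * 0.8,
            S=true_params.S * 1.2,
            H=true_params.H * 0.8,
        )
        res = fit_growth_params(clean_chambers, init=init)
        assert res.rmse < 1e-6
        for name in ("A", "k", "S", "H"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(true_params, name), rel=1e-4
            )

    def test_noisy_fit_recovers_rate_curve(self, noisy_chambers, true_params):
        """Under 0.5 g noise the rate curve r(T) is the identifiable quantity.

        The individual parameters lie on a near-flat likelihood ridge, but
        the fitted temperature-response curve must match the truth across
        the sampled range, and the fit must reach the noise floor.
        """
        init = GrowthModelParams(
            A=true_params.A * 1.2,
            k=true_params.k * 0.8,
            S=true_params.S * 1.2,
            H=true_params.H * 0.8,
        )
        res = fit_growth_params(noisy_chambers, init=init)
        assert res.rmse < 1.0  # noise floor ~0.5 g/plant
        T = np.linspace(287.0, 309.0, 40)
        r_fit = growth_rate(T, res.params)
        r_true = growth_rate(T, true_params)
        # error relative to the peak rate: relative error at the cold/hot
        # extremes is dominated by the tiny rates there
        assert np.max(np.abs(r_fit - r_true)) / r_true.max() < 0.10

    def test_never_worse_than_init(self, noisy_chambers, true_params):
        for factor in (0.8, 1.0, 1.3):
            init = GrowthModelParams(
                A=true_params.A * factor,
                k=true_params.k,
                S=true_params.S * factor,
                H=true_params.H,
            )
            res = fit_growth_params(noisy_chambers, init=init)
            assert res.rmse <= pooled_rmse(noisy_chambers, init) + 1e-12

    def test_one_dimensional_profile_recovers_A(self, true_params):
        # observations on the model curve for a different A; only A free
        target = GrowthModelParams(0.6, true_params.k, true_params.S, true_params.H)
        days = (2.0, 6.0, 10.0, 14.0)
        t_high, t_low = 300.15, 292.15
        r = growth_rate(weighted_day_temperature(t_high, t_low), target)
        weights = tuple(0.5 * (1 + r) ** np.asarray(days))
        ds = ChamberDataset("one", t_high, t_low, days, weights)
        res = fit_growth_params(
            [ds], init=GrowthModelParams(0.4, target.k, target.S, target.H), free=("A",)
        )
        assert res.params.A == pytest.approx(0.6, rel=1e-6)
        assert res.params.k == target.k  # held fixed

    def test_empty_input_rejected(self, true_params):
        with pytest.raises(ValueError):
            fit_growth_params([], init=true_params)


class TestChamberIO:
    def test_csv_round_trip(self, tmp_path, noisy_chambers):
        path = tmp_path / "chambers.csv"
        write_chamber_csv(noisy_chambers, path)
        back = read_chamber_csv(path)
        assert len(back) == len(noisy_chambers)
        by_name = {ds.regime: ds for ds in back}
        for ds in noisy_chambers:
            other = by_name[ds.regime]
            assert other.t_high == pytest.approx(ds.t_high)
            assert np.allclose(other.dry_weights, ds.dry_weights)

    def test_observation_count(self):
        design = SyntheticExperimentDesign(noise_sd=0.0)
        data = synth_chamber_data(design)
        assert len(data) == 10
        assert sum(len(ds.days) for ds in data) == 60
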