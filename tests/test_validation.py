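import numpy as np
import pytest
from scipy.special import gammaln

import apcburden as ab
from oracles import crps_brute, poisson_logpmf


class TestCRPS:
    def test_perfect_deterministic_forecast(self):
        assert ab.crps_ensemble(np.full(100, 3.7), 3.7) == pytest.approx(0.0)

    def test_two_point_ensemble_by_enumeration(self):
        assert ab.crps_ensemble(np.array([0.0, 1.0]), 1.0) == pytest.approx(0.25)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.3
        assert ab.crps_ensemble(x, y) == pytest.approx(crps_brute(x, y), abs=1e-12)

    def test_translation_invariance_and_nonnegativity(self, rng):
        x = rng.normal(2, 1.5, 60)
        y = 1.1
        c = ab.crps_ensemble(x, y)
        assert c >= 0
        assert ab.crps_ensemble(x + 10.0, y + 10.0) == pytest.approx(c, abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ab.crps_ensemble(np.array([1.0]), 0.0)


class TestCoverage:
    def test_all_inside(self):
        iv = np.stack([np.zeros(10), np.ones(10)], axis=-1)
        assert ab.coverage(iv, np.full(10, 0.5)) == 1.0

    def test_half_inside_constructed(self):
        lo = np.zeros(10)
        hi = np.ones(10)
        y = np.array([0.5] * 5 + [2.0] * 5)
        assert ab.coverage(np.stack([lo, hi], -1), y) == 0.5

    def test_boundary_counts_as_covered(self):
        iv = np.array([[0.0, 1.0]])
        assert ab.coverage(iv, np.array([1.0])) == 1.0

    def test_matches_counting_oracle(self, rng):
        lo = rng.normal(0, 1, 50)
        hi = lo + rng.uniform(0.1, 2.0, 50)
        y = rng.normal(0, 1.5, 50)
        expected = sum(1 for a, b, v in zip(lo, hi, y) if a <= v <= b) / 50
        assert ab.coverage(np.stack([lo, hi], -1), y) == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        lo = rng.uniform(0.1, 1.0, 30)
        hi = lo + rng.uniform(0.1, 1.0, 30)
        y = rng.uniform(0.1, 2.0, 30)
        base = ab.coverage(np.stack([lo, hi], -1), y)
        assert ab.coverage(np.stack([np.log(lo), np.log(hi)], -1), np.log(y)) == base

    def test_widening_cannot_decrease_coverage(self, rng):
        lo = rng.normal(0, 1, 40)
        hi = lo + rng.uniform(0.0, 1.0, 40)
        y = rng.normal(0, 1, 40)
        narrow = ab.coverage(np.stack([lo, hi], -1), y)
        wide = ab.coverage(np.stack([lo - 0.5, hi + 0.5], -1), y)
        assert wide >= narrow

    def test_crossed_interval_rejected(self):
        with pytest.raises(ValueError):
            ab.coverage(np.array([[1.0, 0.0]]), np.array([0.5]))


class TestScoreCells:
    def test_observation_at_median_scores_zero_error(self, rng):
        pred = rng.normal(0, 1, (501, 8))
        obs = np.median(pred, axis=0)
        s = ab.score_cells(pred, obs)
        assert s["mae"] == pytest.approx(0.0, abs=1e-12)
        assert s["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert s["coverage95"] == 1.0

    def test_matches_per_cell_metric_oracles(self, rng):
        pred = rng.normal(0, 1, (64, 5))
        obs = rng.normal(0, 1, 5)
        s = ab.score_cells(pred, obs)
        med = np.median(pred, axis=0)
        assert s["mae"] == pytest.approx(np.mean(np.abs(med - obs)), abs=1e-12)
        assert s["rmse"] == pytest.approx(np.sqrt(np.mean((med - obs) ** 2)), abs=1e-12)
        crps = np.mean([crps_brute(pred[:, j], obs[j]) for j in range(5)])
        assert s["crps_mean"] == pytest.approx(crps, abs=1e-12)


class TestInformationCriteria:
    def _degenerate_fit(self):
        """All samples identical: one Poisson cell y=2 with fitted mean 2."""
        grid = ab.LexisGrid(
            counts=np.array([[2.0]]),
            person_years=np.array([[1.0]]),
            age_groups=["0 plus"],
            years=np.array([2000]),
            age_width=1,
        )
        S = 40
        eta = np.full((S, 1, 1), np.log(2.0))
        return ab.APCFit(
            spec=ab.APCModelSpec(sample_count=S),
            grid=grid,
            eta=eta,
            mu=np.full(S, np.log(2.0)),
            age=np.zeros((S, 1)),
            period=np.zeros((S, 1)),
            cohort=np.zeros((S, 1)),
            delta=np.zeros((S, 0)),
            sigma_age=np.full(S, 0.1),
            sigma_period=np.full(S, 0.1),
            sigma_cohort=np.full(S, 0.1),
            phi=None,
            theta_mode=np.zeros(3),
            theta_cov=np.eye(3),
            log_marginal_mode=0.0,
            diagnostics={},
        )

    def test_point_posterior_dic_analytic(self):
        fit = self._degenerate_fit()
        crit = ab.information_criteria(fit)
        # ln p(2 | mean 2) = -2 + 2 ln 2 - ln 2! ; p_D = 0
        expected = -2.0 * (-2.0 + 2.0 * np.log(2.0) - np.log(2.0))
        assert crit["p_d"] == pytest.approx(0.0, abs=1e-10)
        assert crit["dic"] == pytest.approx(expected, abs=1e-10)
        assert crit["dic"] == pytest.approx(2 * 1.3068528194400546, abs=1e-10)

    def test_waic_effective_parameters_nonnegative(self, small_fit):
        crit = ab.information_criteria(small_fit)
        assert crit["p_waic"] >= 0.0

    def test_three_cell_toy_matches_brute_force(self, rng):
        grid = ab.LexisGrid(
            counts=np.array([[3.0, 7.0, 4.0]]),
            person_years=np.array([[10.0, 10.0, 10.0]]),
            age_groups=["0 plus"],
            years=np.arange(2000, 2003),
            age_width=1,
        )
        S = 25
        eta = rng.normal(-0.5, 0.2, (S, 1, 3))
        fit = ab.APCFit(
            spec=ab.APCModelSpec(sample_count=S), grid=grid, eta=eta,
            mu=np.zeros(S), age=np.zeros((S, 1)), period=np.zeros((S, 3)),
            cohort=np.zeros((S, 3)), delta=np.zeros((S, 0)),
            sigma_age=np.full(S, 0.1), sigma_period=np.full(S, 0.1),
            sigma_cohort=np.full(S, 0.1), phi=None,
            theta_mode=np.zeros(3), theta_cov=np.eye(3),
            log_marginal_mode=0.0, diagnostics={},
        )
        crit = ab.information_criteria(fit)
        # brute force with explicit loops
        y = grid.counts.ravel()
        n = grid.person_years.ravel()
        ll = np.array([[poisson_logpmf(y[i], n[i] * np.exp(eta[s, 0, i]))
                        for i in range(3)] for s in range(S)])
        eta_bar = eta[:, 0, :].mean(axis=0)
        ll_bar = sum(poisson_logpmf(y[i], n[i] * np.exp(eta_bar[i])) for i in range(3))
        p_d = 2 * (ll_bar - np.mean(ll.sum(axis=1)))
        dic = -2 * ll_bar + 2 * p_d
        lppd = sum(np.log(np.mean(np.exp(ll[:, i]))) for i in range(3))
        p_w = sum(np.var(ll[:, i]) for i in range(3))
        waic = -2 * (lppd - p_w)
        cpo = sum(-np.log(np.mean(np.exp(-ll[:, i]))) for i in range(3))
        assert crit["dic"] == pytest.approx(dic, abs=1e-10)
        assert crit["waic"] == pytest.approx(waic, abs=1e-10)
        assert crit["cpo_log_sum"] == pytest.approx(cpo, abs=1e-10)


class TestBacktest:
    def test_degenerate_split_rejected(self, small_grid):
        _, _, grid = small_grid
        with pytest.raises(ValueError, match="degenerate"):
            ab.backtest(grid, ab.APCModelSpec(seed=1), split_year=int(grid.years[0]))

    def test_deterministic_given_seed(self, small_grid):
        _, _, grid = small_grid
        spec = ab.APCModelSpec(seed=8, sample_count=200)
        a = ab.backtest(grid, spec, split_year=int(grid.years[3]))
        b = ab.backtest(grid, spec, split_year=int(grid.years[3]))
        assert a.scores == b.scores

    def test_report_fields_and_split(self, small_grid):
        _, _, grid = small_grid
        rep = ab.backtest(grid, ab.APCModelSpec(seed=8, sample_count=200),
                          split_year=int(grid.years[4]))
        assert rep.train_years == (int(grid.years[0]), int(grid.years[4]))
        assert rep.test_years == (int(grid.years[5]), int(grid.years[-1]))
        assert rep.scores["mae"] >= 0 and rep.scores["rmse"] >= abs(0.0)
        assert 0 <= rep.scores["coverage95"] <= 1
        frame = rep.to_frame("both")
        assert set(frame["metric"]) >= {"mae", "rmse", "crps_mean", "coverage95", "dic"}
        assert "back-test" in rep.summary()

    def test_rate_scale_option(self, small_grid):
        _, _, grid = small_grid
        rep = ab.backtest(grid, ab.APCModelSpec(seed=8, sample_count=200),
                          split_year=int(grid.years[4]), scale="rate")
        assert rep.scale == "rate"
        assert rep.scores["mae"] > 0
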