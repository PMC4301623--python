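"""Statistical structure of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from stovewedge import (
    SimulationParams,
    StepWedgeDesign,
    anova_icc,
    calibrate_alpha0,
    detect_episodes,
    generate_cohort,
    seasonal_multiplier,
    simulate_birthweights,
    simulate_diaries,
    simulate_logger_trace,
    simulate_panel,
    summarize_day,
    trend_log_odds,
)


class TestSeasonalMultiplier:
    def test_no_seasonality_is_flat(self):
        params = SimulationParams(season_amplitude=1.0)
        t = np.arange(1, 25)
        assert np.allclose(seasonal_multiplier(t, params), 1.0)

    def test_peak_and_trough_hit_stated_amplitude(self):
        params = SimulationParams()  # peak at month 3 with default phase
        t = np.linspace(0, 12, 4801)
        m = seasonal_multiplier(t, params)
        assert m.max() == pytest.approx(1.05, abs=1e-6)
        assert m.min() == pytest.approx(1 / 1.05, abs=1e-6)
        assert seasonal_multiplier(3.0, params) == pytest.approx(1.05)

    def test_geometric_mean_over_cycle_is_one(self):
        params = SimulationParams()
        t = np.linspace(0, 12, 12_000, endpoint=False)
        assert np.exp(np.mean(np.log(seasonal_multiplier(t, params)))) == pytest.approx(
            1.0, abs=1e-9
        )


class TestTrend:
    def test_none_scenario_is_zero(self):
        params = SimulationParams(trend_scenario="none")
        assert np.all(trend_log_odds(np.arange(1, 25), params) == 0)

    def test_large_trend_boundary_values(self):
        params = SimulationParams(trend_scenario="large")
        assert trend_log_odds(1, params) == pytest.approx(np.log(1.5))
        assert trend_log_odds(11, params) == 0.0
        assert trend_log_odds(24, params) == 0.0
        assert trend_log_odds(6, params) == pytest.approx(np.log(1.5) * 0.5)


class TestCohort:
    def test_zero_mean_gives_empty_cohort(self, default_design):
        params = SimulationParams(mean_children_per_sector=0.0)
        cohort = generate_cohort(default_design, params)
        assert len(cohort) == 0

    def test_sector_sizes_poisson_mean(self, default_design):
        """48 sectors x many seeds: mean size within 3 SE of 35."""
        sizes = []
        for seed in range(30):
            cohort = generate_cohort(
                default_design, SimulationParams(seed=seed)
            )
            sizes.append(cohort.attrs["sector_sizes"].to_numpy())
        sizes = np.concatenate(sizes)
        se = np.sqrt(35 / sizes.size)
        assert abs(sizes.mean() - 35) < 3 * se

    def test_child_effect_variance_matches_parameter(self, default_design):
        params = SimulationParams(mean_children_per_sector=220, seed=1)
        cohort = generate_cohort(default_design, params)
        assert len(cohort) > 10_000
        assert cohort["c_child"].var() == pytest.approx(0.10, rel=0.06)
        # village effects repeat within a sector
        per_sector = cohort.groupby("sector_id")["b_village"].nunique()
        assert (per_sector == 1).all()


class TestPanel:
    @staticmethod
    def _rate_and_se(panel):
        """Annual rate with a cluster-aware (between-sector) standard error."""
        per_sector = panel.groupby("sector_id")["y"].mean() * 12
        return (
            float(panel["y"].mean() * 12),
            float(per_sector.std() / np.sqrt(per_sector.size)),
        )

    def test_null_annual_rate_matches_calibration(self, default_design):
        params = SimulationParams(theta=0.0, seed=8)
        cohort = generate_cohort(default_design, params)
        panel = simulate_panel(default_design, cohort, params)
        rate, se = self._rate_and_se(panel)
        assert abs(rate - 1.0) < 3 * se

    def test_calibration_insensitive_to_amplitude(self):
        """Geometric-mean-preserving seasonality leaves the rate calibrated."""
        p_flat = SimulationParams(season_amplitude=1.0)
        p_seasonal = SimulationParams(season_amplitude=1.5)
        assert calibrate_alpha0(p_flat) != calibrate_alpha0(p_seasonal)
        for params in (p_flat, p_seasonal):
            design = StepWedgeDesign(crossover_month=None)
            cohort = generate_cohort(design, params.with_(seed=4))
            panel = simulate_panel(design, cohort, params.with_(seed=4))
            rate, se = self._rate_and_se(panel)
            assert abs(rate - 1.0) < 3 * se

    def test_theta_recovered_by_raw_stratified_odds(self):
        """At variances 0 / amplitude 1, the exposed:unexposed odds ratio
        converges to exp(theta)."""
        design = StepWedgeDesign.from_wedge_order(list(range(1, 13)))
        params = SimulationParams(
            theta=-0.3,
            var_village=0.0,
            var_child=0.0,
            season_amplitude=1.0,
            mean_children_per_sector=300,
            seed=6,
        )
        cohort = generate_cohort(design, params)
        panel = simulate_panel(design, cohort, params)
        p1 = panel.loc[panel.x == 1, "y"].mean()
        p0 = panel.loc[panel.x == 0, "y"].mean()
        log_or = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
        assert log_or == pytest.approx(-0.3, abs=0.05)

    def test_all_control_design_ignores_theta(self):
        design = StepWedgeDesign(crossover_month=None)
        params = SimulationParams(mean_children_per_sector=5)
        cohort = generate_cohort(design, params)
        a = simulate_panel(design, cohort, params.with_(theta=0.0))
        b = simulate_panel(design, cohort, params.with_(theta=-0.3))
        pd.testing.assert_frame_equal(a, b)

    def test_bit_reproducible_for_fixed_seed(self, default_design):
        params = SimulationParams(seed=123, mean_children_per_sector=5)
        a = simulate_panel(default_design, generate_cohort(default_design, params), params)
        b = simulate_panel(default_design, generate_cohort(default_design, params), params)
        pd.testing.assert_frame_equal(a, b)

    def test_transition_month_dropped_when_configured(self):
        design = StepWedgeDesign.from_wedge_order(list(range(1, 13)), transition="drop")
        params = SimulationParams(mean_children_per_sector=3, seed=2)
        cohort = generate_cohort(design, params)
        panel = simulate_panel(design, cohort, params)
        for g, m in design.crossover_month.items():
            sub = panel[panel["group_id"] == g]
            assert m not in set(sub["period"])

    def test_village_and_child_spread_match_stated_glosses(self, default_design):
        """Between-village spread ~ +/-2*sqrt(.025), between-child ~ +/-2*sqrt(.10)
        on the log-odds scale."""
        params = SimulationParams(mean_children_per_sector=200, seed=5)
        cohort = generate_cohort(default_design, params)
        b = cohort.groupby("sector_id")["b_village"].first()
        assert np.std(b) == pytest.approx(np.sqrt(0.025), rel=0.35)
        assert np.quantile(np.abs(cohort["c_child"]), 0.954) == pytest.approx(
            2 * np.sqrt(0.10), rel=0.1
        )


class TestDiaries:
    def test_noise_free_single_episode_is_one_clean_run(self):
        cohort = pd.DataFrame({"child_id": [1]})
        diary, truth = simulate_diaries(cohort, episode_rate=1.0, n_days=60, seed=3)
        core = diary["fever"] | diary["fast_difficult_breathing"]
        runs = (core != core.shift()).cumsum()[core]
        assert runs.nunique() == len(truth)

    def test_planted_episodes_separated_by_seven_clear_days(self):
        cohort = pd.DataFrame({"child_id": range(30)})
        diary, truth = simulate_diaries(
            cohort, episode_rate=6.0, n_days=365, noise_rate=5.0, seed=9
        )
        for child, eps in truth.groupby("child_id"):
            eps = eps.sort_values("start_date")
            gaps = (
                eps["start_date"].iloc[1:].to_numpy()
                - eps["end_date"].iloc[:-1].to_numpy()
            ) / np.timedelta64(1, "D")
            assert (gaps >= 8).all()  # end->start difference 8 = 7 clear days

    def test_detector_round_trip_recovers_ground_truth(self):
        cohort = pd.DataFrame({"child_id": range(25)})
        diary, truth = simulate_diaries(
            cohort, episode_rate=3.0, n_days=365, noise_rate=4.0, seed=17
        )
        detected = []
        for child, child_diary in diary.groupby("child_id"):
            for ep in detect_episodes(child_diary):
                detected.append(
                    (child, ep.start_date, ep.end_date)
                )
        expected = [
            (r.child_id, r.start_date, r.end_date) for r in truth.itertuples()
        ]
        assert sorted(detected) == sorted(expected)


class TestLoggerTrace:
    def test_constant_when_no_events_or_noise(self):
        trace, events = simulate_logger_trace(
            n_cooking_events=0, baseline_level=80.0, noise_sd=0.0, seed=0
        )
        assert len(events) == 0
        assert np.allclose(trace["value"], 80.0)

    def test_length_matches_cadence(self):
        trace, _ = simulate_logger_trace(duration_h=18, seed=1)
        assert len(trace) == 18 * 360
        assert np.allclose(np.diff(trace["timestamp"]), 10.0)

    def test_sit_round_trip_within_one_interval_per_boundary(self):
        trace, events = simulate_logger_trace(
            n_cooking_events=2,
            baseline_level=50.0,
            event_magnitude=400.0,
            noise_sd=0.0,
            seed=12,
        )
        assert len(events) == 2
        summary = summarize_day(trace)
        detected = np.array(summary.sit_intervals)
        for ev in events.itertuples():
            lo = int(ev.start_s // 600) + 1
            hi = int(ev.end_s // 600) + 1
            inside = detected[(detected >= lo) & (detected <= hi)]
            # every planted interval is found up to one interval per boundary
            assert inside.min() <= lo + 1 and inside.max() >= hi - 1
        # nothing detected far away from the planted events
        for k in detected:
            near_any = any(
                int(ev.start_s // 600) <= k + 1 and k - 1 <= int(ev.end_s // 600) + 1
                for ev in events.itertuples()
            )
            assert near_any


class TestBirthweights:
    def test_zero_icc_is_iid_normal(self):
        df = simulate_birthweights(n_clusters=40, cluster_sizes=50, icc=0.0, seed=3)
        assert df["weight_g"].mean() == pytest.approx(2700, abs=3 * 437 / np.sqrt(2000))
        assert anova_icc(df["weight_g"], df["cluster_id"]) == pytest.approx(0, abs=0.03)

    def test_marginal_sd_matches_parameter(self):
        df = simulate_birthweights(n_clusters=500, cluster_sizes=100, seed=4)
        n = len(df)
        assert df["weight_g"].std() == pytest.approx(437, abs=3 * 437 / np.sqrt(2 * n))

    def test_anova_icc_recovers_default_parameter(self):
        iccs = [
            anova_icc(
                *simulate_birthweights(n_clusters=500, cluster_sizes=30, seed=s)[
                    ["weight_g", "cluster_id"]
                ].T.values
            )
            for s in range(8)
        ]
        assert np.mean(iccs) == pytest.approx(0.03357, abs=3 * np.std(iccs) / np.sqrt(8))

    def test_effect_shifts_treated_clusters(self):
        treated = [True] * 20 + [False] * 20
        df = simulate_birthweights(
            n_clusters=40, cluster_sizes=200, effect_g=-100.0, treated=treated, seed=5
        )
        diff = (
            df.loc[df.arm == "intervention", "weight_g"].mean()
            - df.loc[df.arm == "control", "weight_g"].mean()
        )
        assert diff == pytest.approx(-100, abs=35)

    def test_invalid_icc_rejected(self):
        with pytest.raises(ValueError):
            simulate_birthweights(icc=1.0)
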