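"""Spline basis, Laplace GLMM engine, robust variance, and birthweight fits."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from stovewedge import (
    ModelSpec,
    SimulationParams,
    StepWedgeDesign,
    SteppedWedgeLogit,
    fit_birthweight,
    generate_cohort,
    natural_spline_basis,
    robust_variance,
    sensitivity_over_v,
    simulate_birthweights,
    simulate_panel,
)
from stovewedge.glmm import fit_agq_single_level


class TestSplineBasis:
    def test_v2_spans_linear_functions(self):
        t = np.arange(1.0, 25.0)
        basis = natural_spline_basis(t, 2)
        design = np.column_stack([np.ones_like(t), basis])
        coef, res, *_ = np.linalg.lstsq(design, t, rcond=None)
        assert np.allclose(design @ coef, t, atol=1e-8)

    @pytest.mark.parametrize("v", [2, 4, 8, 12])
    def test_column_count_is_v(self, v):
        basis = natural_spline_basis(np.linspace(1, 24, 200), v)
        assert basis.shape[1] == v

    def test_second_derivative_continuous_at_knots(self):
        """Finite-difference second derivative has no jumps at the knots."""
        t = np.linspace(1, 24, 46001)
        h = t[1] - t[0]
        basis = natural_spline_basis(t, 5, standardize=False)
        d2 = (basis[2:] - 2 * basis[1:-1] + basis[:-2]) / h**2
        jumps = np.abs(np.diff(d2, axis=0)).max(axis=1)
        assert jumps.max() < 0.05  # cubic pieces: d2 is piecewise linear

    def test_linear_beyond_boundary_knots(self):
        t_in = np.linspace(1, 24, 100)
        basis_cols = natural_spline_basis(
            np.concatenate([t_in, [30.0, 40.0, 50.0]]), 6, boundary=(1, 24),
            standardize=False,
        )
        outside = basis_cols[-3:]
        # second differences over equal steps outside the boundary are 0
        second_diff = outside[2] - 2 * outside[1] + outside[0]
        assert np.allclose(second_diff, 0.0, atol=1e-8)

    def test_v0_empty_and_v1_rejected(self):
        assert natural_spline_basis(np.arange(5.0), 0).shape == (5, 0)
        with pytest.raises(ValueError):
            natural_spline_basis(np.arange(5.0), 1)
        with pytest.raises(ValueError, match="distinct"):
            natural_spline_basis(np.full(5, 3.0), 2)

    def test_insufficient_distinct_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            natural_spline_basis(np.array([1.0, 2.0, 3.0]), 4)


class TestLaplaceFit:
    def test_null_data_with_no_random_effects(self):
        """Variances ~0 and theta near 0 when the truth is a plain logistic."""
        design = StepWedgeDesign.from_wedge_order(list(range(1, 13)))
        params = SimulationParams(
            theta=0.0, var_village=0.0, var_child=0.0, season_amplitude=1.0,
            mean_children_per_sector=60, seed=42,
        )
        cohort = generate_cohort(design, params)
        panel = simulate_panel(design, cohort, params)
        fit = SteppedWedgeLogit(panel, v=0).fit()
        assert fit.converged
        assert abs(fit.theta_hat) < 2 * fit.se_model
        assert fit.var_village_hat < 0.02
        assert fit.var_child_hat < 0.02

    def test_recovers_simulated_effect(self, small_panel):
        _, params, _, panel = small_panel
        fit = SteppedWedgeLogit(panel, v=8).fit()
        assert fit.converged
        assert fit.theta_hat == pytest.approx(-0.3, abs=2.5 * fit.se_model)

    def test_laplace_agrees_with_adaptive_quadrature(self):
        """Single-level model: Laplace vs AGQ theta within 0.01."""
        design = StepWedgeDesign.from_wedge_order(
            list(range(1, 13)), sectors_per_group=1
        )
        params = SimulationParams(
            theta=-0.3, var_child=0.0, var_village=0.10,
            mean_children_per_sector=12, seed=31,
        )
        cohort = generate_cohort(design, params)
        panel = simulate_panel(design, cohort, params)
        lap = SteppedWedgeLogit(panel, v=0, include_child_effect=False).fit()
        agq = fit_agq_single_level(panel, v=0)
        assert abs(lap.theta_hat - agq["theta_hat"]) < 0.01

    def test_agrees_with_glmer_reference(self, small_panel, tmp_path):
        """Independent cross-check against lme4::glmer (Laplace) on one panel."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        _, _, _, panel = small_panel
        fit = SteppedWedgeLogit(panel, v=0).fit()
        csv = tmp_path / "panel.csv"
        panel.to_csv(csv, index=False)
        script = tmp_path / "ref.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                f <- glmer(y ~ x + (1 | sector_id) + (1 | child_id),
                           data = d, family = binomial)
                cat(fixef(f)["x"], sqrt(vcov(f)["x", "x"]), sep = "\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        theta_ref, se_ref = map(float, out.stdout.strip().split())
        assert fit.theta_hat == pytest.approx(theta_ref, abs=0.005)
        assert fit.se_model == pytest.approx(se_ref, rel=0.05)

    def test_constant_exposure_rejected(self, small_panel):
        _, _, _, panel = small_panel
        null_panel = panel.assign(x=0)
        with pytest.raises(ValueError, match="constant"):
            SteppedWedgeLogit(null_panel, v=2)

    def test_missing_column_is_schema_error(self):
        with pytest.raises(ValueError, match="x"):
            SteppedWedgeLogit(
                pd.DataFrame(
                    {"child_id": [1], "sector_id": [1], "group_id": [1],
                     "period": [1], "y": [0]}
                ),
                v=0,
            )


class TestRobustVariance:
    def test_single_cluster_rejected(self):
        panel = pd.DataFrame(
            {
                "child_id": np.repeat(np.arange(40), 4),
                "sector_id": 1,
                "group_id": 1,
                "period": np.tile([1, 2, 3, 4], 40),
                "x": np.tile([0, 0, 1, 1], 40),
                "y": (np.arange(160) * 7 % 11 < 3).astype(int),
            }
        )
        fit = SteppedWedgeLogit(panel, v=0).fit()
        assert fit.se_robust is None  # cannot be formed, but the fit survives
        with pytest.raises(ValueError, match="single cluster"):
            robust_variance(fit)

    def test_correct_specification_ratio_near_one(self, small_panel):
        _, _, _, panel = small_panel
        fit = SteppedWedgeLogit(panel, v=2).fit()
        assert 0.6 < fit.robust_ratio < 1.5

    def test_unmodelled_correlation_inflates_robust_se(self, small_panel):
        """Duplicating every observation (perfectly correlated pairs the
        model treats as independent) halves the model-based variance but not
        the sandwich: the ratio detects the unmodelled dependence."""
        _, _, _, panel = small_panel
        doubled = pd.concat([panel, panel], ignore_index=True)
        fit = SteppedWedgeLogit(doubled, v=2, include_child_effect=False).fit()
        assert fit.robust_ratio > 1.2

    def test_group_level_aggregation_supported(self):
        order = list(range(1, 13))
        design = StepWedgeDesign.from_wedge_order(order, sectors_per_group=2)
        params = SimulationParams(theta=-0.2, mean_children_per_sector=6, seed=15)
        cohort = generate_cohort(design, params)
        panel = simulate_panel(design, cohort, params)
        fit = SteppedWedgeLogit(panel, v=2).fit()
        se_sector = fit.se_robust  # 24 sector clusters
        robust_variance(fit, cluster_level="group")  # 12 group clusters
        assert fit.se_robust > 0
        assert fit.se_robust != se_sector


class TestSensitivity:
    def test_one_row_per_v_and_stability_without_trend(self, small_panel):
        _, _, _, panel = small_panel
        table = sensitivity_over_v(panel, v_list=[4, 6, 8])
        assert list(table["v"]) == [4, 6, 8]
        thetas = table["theta_hat"]
        assert thetas.max() - thetas.min() < table["se_model"].min()

    def test_rank_deficient_v_skipped_with_warning(self, small_panel):
        _, _, _, panel = small_panel
        short = panel[panel["period"] <= 8]  # 8 distinct periods
        with pytest.warns(UserWarning, match="skipped"):
            table = sensitivity_over_v(short, v_list=[4, 10])
        assert table.loc[table.v == 10, "theta_hat"].isna().all()
        assert np.isfinite(table.loc[table.v == 4, "theta_hat"]).all()


class TestBirthweight:
    def test_lbw_cut_is_strict_at_2500(self):
        """Weights of exactly 2500 g are not low birthweight: replacing them
        by 2500.1 g leaves the LBW fit unchanged."""
        treated = [True] * 20 + [False] * 20
        df = simulate_birthweights(
            n_clusters=40, cluster_sizes=25, effect_g=-120.0, treated=treated, seed=3
        )
        df.loc[df.index[:50], "weight_g"] = 2500.0
        nudged = df.copy()
        nudged.loc[nudged.index[:50], "weight_g"] = 2500.1
        res_a = fit_birthweight(df, outcome="lbw")
        res_b = fit_birthweight(nudged, outcome="lbw")
        assert res_a.effect == pytest.approx(res_b.effect, abs=1e-8)
        below = df.copy()
        below.loc[below.index[:50], "weight_g"] = 2499.9
        res_c = fit_birthweight(below, outcome="lbw")
        assert res_c.effect != pytest.approx(res_a.effect, abs=1e-6)

    def test_continuous_effect_recovery(self):
        treated = [True] * 40 + [False] * 40
        df = simulate_birthweights(
            n_clusters=80, cluster_sizes=30, effect_g=-100.0, treated=treated, seed=8
        )
        res = fit_birthweight(df, outcome="continuous")
        assert res.effect == pytest.approx(-100.0, abs=2 * res.se_model)
        assert res.se_robust > 0

    def test_icc_estimate_consistent_with_generator(self):
        df = simulate_birthweights(
            n_clusters=400, cluster_sizes=30, icc=0.03357, seed=13,
            treated=[i % 2 == 0 for i in range(400)],
        )
        res = fit_birthweight(df, outcome="continuous")
        assert res.icc == pytest.approx(0.03357, abs=0.015)

    def test_lbw_effect_recovery(self):
        treated = [True] * 60 + [False] * 60
        df = simulate_birthweights(
            n_clusters=120, cluster_sizes=40, effect_g=-150.0, treated=treated, seed=21
        )
        res = fit_birthweight(df, outcome="lbw")
        # -150 g on a Normal(2700, 437) shifts P(<2500) from ~0.32 to ~0.37;
        # the implied log-odds effect is ~ +0.23
        assert res.effect == pytest.approx(0.23, abs=2.5 * res.se_model)

    def test_degenerate_cluster_structure_rejected(self):
        df = simulate_birthweights(n_clusters=2, cluster_sizes=10, seed=1)
        with pytest.raises(ValueError, match="clusters per arm"):
            fit_birthweight(df)


class TestModelSpec:
    def test_invalid_v_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(v=1)
        with pytest.raises(ValueError):
            ModelSpec(v=13)

    def test_summary_renders(self, small_panel):
        _, _, _, panel = small_panel
        fit = SteppedWedgeLogit(panel, v=2).fit()
        text = fit.summary()
        assert "theta" in text and "sigma2 village" in text
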