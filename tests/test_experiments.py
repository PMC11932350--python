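"""Replication loop, metrics, grids, extrapolation helper and CLI plumbing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from radconfound import (
    ScenarioConfig,
    SmokingModel,
    coverage,
    extrapolate_or_per_gray,
    generate_cohort,
    percent_overestimation,
    relative_bias,
    run_grid,
    run_scenario,
    summaries_to_frame,
    write_results_csv,
)
from radconfound.estimators import AnalysisSpec, cox_fit

COX_ARMS = (("cox", "adjusted"), ("cox", "unadjusted"))


class TestMetrics:
    def test_relative_bias_zero_when_exact(self):
        assert relative_bias([0.5, 0.5], 0.5, 0.3) == 0.0

    def test_relative_bias_arithmetic(self):
        # a coefficient shift of 0.3234 over ERR 0.3 is a relative bias of 1.078
        beta_true = math.log(1.3)
        assert relative_bias([beta_true + 0.3234], beta_true, 0.3) == pytest.approx(1.078)

    def test_relative_bias_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            relative_bias([], 0.0, 0.3)
        with pytest.raises(ValueError):
            relative_bias([0.1], 0.0, 0.0)

    def test_coverage_one_for_huge_se(self, rng):
        betas = rng.normal(0.0, 1.0, 100)
        assert coverage(betas, np.full(100, 1e6), 0.0) == 1.0

    def test_coverage_matches_closed_form_under_shift(self, rng):
        # biased normal estimator with known SE: coverage has a Phi closed form
        n, shift, se = 20_000, 1.2, 1.0
        betas = rng.normal(shift, se, n)
        expected = norm.cdf(1.959964 - shift) - norm.cdf(-1.959964 - shift)
        got = coverage(betas, np.full(n, se), 0.0)
        assert abs(got - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_coverage_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            coverage([], [], 0.0)
        with pytest.raises(ValueError):
            coverage([0.1], [0.0], 0.0)


class TestRunScenario:
    def test_single_replication_equals_direct_fit(self, small_config):
        cfg = small_config.replace(n_reps=1)
        summary = run_scenario(cfg, arms=COX_ARMS)
        cohort = generate_cohort(cfg, 0)
        direct = cox_fit(cohort, AnalysisSpec("cox", ("dose",)))
        arm = summary.arm("cox", "unadjusted")
        assert arm.mean_relative_bias == pytest.approx(
            (direct.beta_r_hat - cfg.beta_r_true) / cfg.err_true
        )
        assert arm.mean_se == pytest.approx(direct.se)
        assert arm.n_converged == 1

    def test_deterministic_and_worker_invariant(self, small_config):
        cfg = small_config.replace(n_reps=4, cohort_size=600)
        a = run_scenario(cfg, arms=COX_ARMS)
        b = run_scenario(cfg, arms=COX_ARMS)
        c = run_scenario(cfg, arms=COX_ARMS, n_jobs=2)
        for model, analysis in COX_ARMS:
            assert a.arm(model, analysis) == b.arm(model, analysis)
            assert a.arm(model, analysis) == c.arm(model, analysis)


class TestRunGrid:
    def test_empty_grid_runs_the_base_scenario(self, small_config):
        cfg = small_config.replace(n_reps=2, cohort_size=600)
        out = run_grid(cfg, {}, arms=COX_ARMS)
        assert len(out) == 1
        assert out[0].config == cfg

    def test_per_axis_sweep_sizes_add(self, small_config):
        cfg = small_config.replace(n_reps=1, cohort_size=600)
        out = run_grid(
            cfg,
            {
                "smoking_model.or_at_1gy": [1.0, 4.0, 32.0],
                "cohort_size": [600, 900],
            },
            arms=(("cox", "unadjusted"),),
        )
        assert len(out) == 3 + 2

    def test_cartesian_sweep_sizes_multiply(self, small_config):
        cfg = small_config.replace(n_reps=1, cohort_size=600)
        out = run_grid(
            cfg,
            {"smoking_model.or_at_1gy": [1.0, 32.0], "cohort_size": [600, 900]},
            mode="cartesian",
            arms=(("cox", "unadjusted"),),
        )
        assert len(out) == 4

    def test_unknown_key_raises(self, small_config):
        with pytest.raises(KeyError):
            run_grid(small_config, {"no_such_knob": [1]}, arms=COX_ARMS)


class TestExtrapolateOddsRatio:
    def test_equal_proportions_give_unity(self):
        assert extrapolate_or_per_gray(0.4, 0.4, 0.2) == pytest.approx(1.0)

    def test_observed_odds_ratio_between_dose_groups(self):
        assert round(extrapolate_or_per_gray(0.63, 0.78, 1.0), 2) == 2.08

    def test_extrapolation_to_one_sievert(self):
        assert round(extrapolate_or_per_gray(0.63, 0.78, 0.2), 2) == 39.14

    def test_boundary_proportions_raise(self):
        for p_low, p_high in ((0.0, 0.5), (0.5, 1.0)):
            with pytest.raises(ValueError):
                extrapolate_or_per_gray(p_low, p_high, 1.0)

    def test_percent_overestimation_of_unadjusted_err(self):
        assert percent_overestimation(0.80, 0.29) == pytest.approx(175.86, abs=0.01)


class TestResultsCsv:
    def test_round_trip_values(self, small_config, tmp_path):
        cfg = small_config.replace(n_reps=2, cohort_size=600)
        summaries = run_grid(cfg, {"smoking_model.or_at_1gy": [1.0, 32.0]}, arms=COX_ARMS)
        path = tmp_path / "results.csv"
        write_results_csv(summaries, path)
        df = pd.read_csv(path)
        assert len(df) == 2
        frame = summaries_to_frame(summaries)
        np.testing.assert_allclose(
            df["cox_a2_bias"], frame["cox_a2_bias"], rtol=1e-6
        )
        # one wide row per scenario with per-arm metric columns
        for col in ("cox_a1_bias", "cox_a1_se", "cox_a1_coverage", "cox_a2_coverage"):
            assert col in df.columns

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            write_results_csv([], "unused.csv")


class TestConfigFiles:
    def test_yaml_scenario_round_trip(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(
            "cohort_size: 700\n"
            "n_reps: 2\n"
            "seed: 9\n"
            "smoking_model: {baseline_prob: 0.3, or_at_1gy: 4.0}\n"
            "risk_model: {beta_r: 0.2623643, beta_s: 0.4700036, beta_u: 0.0}\n"
        )
        cfg = ScenarioConfig.from_yaml(path)
        assert cfg.cohort_size == 700
        assert cfg.smoking_model == SmokingModel(baseline_prob=0.3, or_at_1gy=4.0)

    def test_grid_file(self, tmp_path):
        from radconfound.config import load_grid

        path = tmp_path / "sweep.yaml"
        path.write_text(
            "cohort_size: 700\nn_reps: 1\n"
            "grid:\n  smoking_model.or_at_1gy: [1.0, 32.0]\n"
        )
        cfg, grid = load_grid(path)
        assert cfg.cohort_size == 700
        assert grid == {"smoking_model.or_at_1gy": [1.0, 32.0]}

    def test_dotted_replace(self):
        cfg = ScenarioConfig()
        out = cfg.replace(**{"smoking_model.or_at_1gy": 2.0, "cohort_size": 500})
        assert out.smoking_model.or_at_1gy == 2.0
        assert out.cohort_size == 500
        assert cfg.smoking_model.or_at_1gy == 32.0  # original untouched


class TestCli:
    def test_simulate_writes_summary_csv(self, tmp_path):
        from click.testing import CliRunner

        from radconfound.cli import main

        out = tmp_path / "one.csv"
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["simulate", "--reps", "2", "--cohort-size", "600", "--seed", "3",
             "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        assert len(df) == 1
        assert "cox_a2_bias" in df.columns

    def test_sweep_from_config_file(self, tmp_path):
        from click.testing import CliRunner

        from radconfound.cli import main

        cfg = tmp_path / "sweep.yaml"
        cfg.write_text(
            "cohort_size: 600\nn_reps: 1\nseed: 5\n"
            "grid:\n  smoking_model.or_at_1gy: [1.0, 32.0]\n"
        )
        out = tmp_path / "sweep.csv"
        runner = CliRunner()
        result = runner.invoke(main, ["sweep", "--config", str(cfg), "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert len(pd.read_csv(out)) == 2
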