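import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import handmap as hm
from handmap import trajectory as traj


def analytic_trace(func, n=301, duration=1.2, scale=211.0):
    """Trace sampled on a grid containing the 30 cut points exactly."""
    y_unit = np.arange(n) / (n - 1)
    return pd.DataFrame(
        {"t_s": y_unit * duration, "x_mm": func(y_unit), "y_mm": y_unit * scale}
    )


class TestTemplates:
    @pytest.mark.parametrize("alpha, beta", [(0, 0), (1, 0.8), (-1, -0.9), (0.5, 0.3)])
    def test_endpoints(self, alpha, beta):
        tpl = hm.make_template(alpha, beta)
        assert tpl(0.0) == pytest.approx(0.0, abs=1e-9)
        assert tpl(1.0) == pytest.approx(alpha * 211.0, abs=1e-9)

    def test_familiarization_curve_midpoint(self):
        # (alpha=0, beta=0.1): x(0.5) = 0.1 units = 21.1 mm
        tpl = hm.make_template(0.0, 0.1)
        assert tpl(0.5) == pytest.approx(21.1)

    def test_default_set_properties(self):
        templates = hm.default_template_set()
        assert len(templates) == 15
        assert all(-1 <= t.alpha <= 1 for t in templates)
        assert all(-0.9 <= t.beta <= 0.8 for t in templates)
        assert (0.0, 0.1) not in {(t.alpha, t.beta) for t in templates}


class TestValidation:
    def test_straight_comfortable_movement_is_valid(self):
        # 275 mm in 1.2 s ~ 229 mm/s, above the 165 mm/s floor
        trace = analytic_trace(lambda y: 0 * y, scale=275.0)
        ok, reasons = traj.validate_trial(trace)
        assert ok and reasons == []

    def test_slow_movement_flagged(self):
        trace = analytic_trace(lambda y: 0 * y, duration=2.0, scale=211.0)
        ok, reasons = traj.validate_trial(trace)  # ~105 mm/s
        assert not ok and reasons == ["slow"]

    def test_backward_step_flagged(self):
        trace = analytic_trace(lambda y: 0 * y, scale=275.0)
        trace.loc[150, "y_mm"] = trace.loc[149, "y_mm"] - 5.0
        ok, reasons = traj.validate_trial(trace)
        assert not ok and "backward" in reasons

    def test_movement_before_go_cue_flagged(self):
        trace = analytic_trace(lambda y: 0 * y, scale=275.0)
        pre = pd.DataFrame({"t_s": [-0.1, -0.05], "x_mm": [0.0, 0.0], "y_mm": [0.0, 12.0]})
        ok, reasons = traj.validate_trial(pd.concat([pre, trace], ignore_index=True))
        assert not ok and "early-start" in reasons

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            traj.validate_trial(pd.DataFrame({"t_s": [0.0], "x_mm": [0.0], "y_mm": [0.0]}))


class TestRmse:
    def test_trace_equal_to_template_scores_zero(self):
        tpl = hm.make_template(0.5, 0.3)
        trace = analytic_trace(tpl)
        assert traj.trajectory_rmse(trace, tpl) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d_cm", [0.5, 1.0, 2.5])
    def test_constant_offset_closed_form(self, d_cm):
        tpl = hm.make_template(0.0, 0.0)
        trace = analytic_trace(lambda y: 0 * y + 10 * d_cm)
        assert traj.trajectory_rmse(trace, tpl) == pytest.approx(
            d_cm * np.sqrt(30), abs=1e-9
        )

    def test_beta_only_offset_closed_form(self):
        """sum_{k=1..30} sin^2(pi k/30) = 15 exactly, amplitude 2.11 cm."""
        tpl0 = hm.make_template(0.0, 0.0)
        trace = analytic_trace(hm.make_template(0.0, 0.1))
        assert traj.trajectory_rmse(trace, tpl0) == pytest.approx(
            2.11 * np.sqrt(15), abs=1e-9
        )

    def test_normalized_variant_divides_by_segments(self):
        tpl = hm.make_template(0.0, 0.0)
        trace = analytic_trace(lambda y: 0 * y + 10.0)
        assert traj.trajectory_rmse(trace, tpl, normalized=True) == pytest.approx(1.0)

    def test_invariant_under_time_reparameterization(self):
        tpl = hm.make_template(0.3, -0.4)
        trace = analytic_trace(lambda y: tpl(y) + 5 * np.sin(2 * np.pi * y))
        # squash time nonlinearly: same (x, y) path, different sampling in y
        u = np.linspace(0, 1, 500) ** 1.7
        warped = pd.DataFrame(
            {
                "t_s": np.linspace(0, 1.2, 500),
                "x_mm": np.interp(u, trace.y_mm / 211.0, trace.x_mm),
                "y_mm": u * 211.0,
            }
        )
        a = traj.trajectory_rmse(trace, tpl)
        b = traj.trajectory_rmse(warped, tpl)
        assert b == pytest.approx(a, abs=0.02)

    def test_cut_points_match_dense_resampling_oracle(self):
        """Linear interpolation at k/30 vs brute-force dense resampling."""
        tpl = hm.make_template(0.2, 0.6)
        trace = analytic_trace(lambda y: tpl(y) + 3 * y * (1 - y), n=601)
        dense_y = np.linspace(0, 1, 600001)
        dense_x = np.interp(dense_y, trace.y_mm / 211.0, trace.x_mm)
        cuts = np.arange(1, 31) / 30
        oracle = dense_x[np.searchsorted(dense_y, cuts)]
        ours = traj._cut_point_x(trace, 211.0)
        assert np.allclose(ours, oracle, atol=1e-9)

    def test_incomplete_trace_rejected(self):
        tpl = hm.make_template(0.0, 0.0)
        trace = analytic_trace(lambda y: 0 * y)
        with pytest.raises(ValueError, match="before the final cut point"):
            traj.trajectory_rmse(trace.iloc[:200], tpl)

    def test_rmse_bounds_endpoint_deviation(self):
        tpl = hm.make_template(0.0, 0.0)
        trace = analytic_trace(lambda y: 8.0 * y)
        rmse = traj.trajectory_rmse(trace, tpl)
        assert rmse**2 >= traj.endpoint_error(trace, tpl) ** 2


class TestEndpointError:
    def test_identical_curves_zero(self):
        tpl = hm.make_template(0.4, -0.2)
        assert traj.endpoint_error(analytic_trace(tpl), tpl) == pytest.approx(0, abs=1e-9)

    def test_constant_offset_one_cm(self):
        tpl = hm.make_template(0.0, 0.0)
        trace = analytic_trace(lambda y: 0 * y + 10.0)
        assert traj.endpoint_error(trace, tpl) == pytest.approx(1.0, abs=1e-9)

    def test_endpoint_immune_to_curvature_perturbation(self):
        tpl = hm.make_template(0.5, 0.0)
        trace = analytic_trace(lambda y: tpl(y) + 30 * np.sin(np.pi * y))
        assert traj.endpoint_error(trace, tpl) == pytest.approx(0.0, abs=1e-9)


class TestSandwichTargets:
    def test_straight_midline_template_selects_middle_columns(self, grid):
        sel = traj.sandwich_targets(hm.make_template(0.0, 0.0), grid)
        assert len(sel) == 10
        assert all(c in (9, 10) for _, c in sel)  # columns at x = +-12.19 mm
        assert sorted({r for r, _ in sel}) == [0, 1, 2, 3, 4]

    def test_template_right_of_grid_clamps_to_rightmost_columns(self, grid):
        sel = traj.sandwich_targets(hm.make_template(2.0, 0.0), grid)
        # at deep rows x = 2*y*211 exceeds the rightmost column (231.6 mm)
        deep = [c for r, c in sel if r == 4]
        assert deep == [18, 19]

    def test_uniform_map_local_error_equals_magnitude(self, uniform_map, grid):
        tpl = hm.make_template(0.0, 0.3)
        assert traj.local_localization_error(uniform_map, tpl, grid) == pytest.approx(0.5)
        assert traj.endpoint_localization_error(uniform_map, tpl, grid) == pytest.approx(0.5)

    def test_endpoint_targets_bracket_template_end(self, grid):
        sel_mid = hm.make_template(0.0, 0.5)
        m = hm.ErrorMap(errors=np.zeros((2, 5, 20)))
        m.errors[0, 4, 9] = 2.0
        m.errors[0, 4, 10] = 4.0
        # endpoint at x=0 -> far-row targets at columns 10 and 11 (1-based)
        assert traj.endpoint_localization_error(m, sel_mid, grid) == pytest.approx(3.0)

    def test_endpoint_beyond_grid_edge_clamps(self, grid):
        m = hm.ErrorMap(errors=np.zeros((2, 5, 20)))
        m.errors[0, 4, 18] = 1.0
        m.errors[0, 4, 19] = 3.0
        assert traj.endpoint_localization_error(
            m, hm.make_template(1.5, 0.0), grid
        ) == pytest.approx(2.0)


class TestSubjectDummyRegression:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(0)
        subj = np.repeat(np.arange(5), 15)
        offsets = rng.normal(0, 2, 5)[subj]
        x = rng.uniform(1, 3, len(subj))
        y = 2.0 * x + offsets
        out = traj.subject_dummy_regression(y, x, subj)
        assert out["slope"] == pytest.approx(2.0, abs=1e-9)
        assert out["ci95"][1] - out["ci95"][0] == pytest.approx(0.0, abs=1e-6)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        subj = np.repeat(np.arange(26), 15)
        x = rng.uniform(1, 3, len(subj))
        y = x + rng.normal(0, 0.5, len(subj))
        out = traj.subject_dummy_regression(y, x, subj)
        assert out["df"] == 390 - 26 - 1

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm_api
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(2)
        subj = np.repeat(np.arange(6), 10)
        x = rng.uniform(0, 1, 60)
        y = 1.5 * x + rng.normal(0, 0.3, 60) + subj * 0.2
        out = traj.subject_dummy_regression(y, x, subj)
        df = pd.DataFrame({"y": y, "x": x, "subj": subj.astype(str)})
        fit = smf.ols("y ~ x + C(subj) - 1", data=df).fit()
        assert out["slope"] == pytest.approx(fit.params["x"], abs=1e-9)
        assert out["p"] == pytest.approx(fit.pvalues["x"], abs=1e-9)
        lo, hi = fit.conf_int().loc["x"]
        assert out["ci95"] == pytest.approx((lo, hi), abs=1e-9)

    def test_null_coverage(self):
        """With x independent of y, the 95% CI covers 0 about 95% of the time."""
        rng = np.random.default_rng(3)
        covered = 0
        reps = 500
        subj = np.repeat(np.arange(8), 10)
        for _ in range(reps):
            x = rng.uniform(0, 1, 80)
            y = rng.normal(0, 1, 80) + subj * 0.3
            lo, hi = traj.subject_dummy_regression(y, x, subj)["ci95"]
            covered += lo <= 0 <= hi
        assert 0.92 < covered / reps < 0.98

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            traj.subject_dummy_regression(np.arange(4.0), np.arange(4.0), np.zeros(4))


class TestMotorLocalizationCorrelation:
    def test_perfect_linear_relation(self):
        x = np.linspace(1, 2, 10)
        out = traj.motor_vs_localization_correlation(x, x, method="pearson")
        assert out["r"] == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            traj.motor_vs_localization_correlation(np.ones(5), np.arange(5.0))

    def test_strong_coupling_yields_high_correlation(self, grid):
        """Power check: with motor noise driven by the localization field
        and all other error sources turned down, the across-subject
        correlation is strong."""
        from handmap.synthetic import GroupBias

        hits = 0
        n_cohorts = 10
        for seed in range(n_cohorts):
            cfg = hm.CohortConfig(
                n_subjects=12, seed=seed, coupling=1.0,
                motor_b0=0.5, motor_b1=0.0, motor_skill_sd=0.0, noise_sd=1.0,
                group_bias=GroupBias(rightward_gain=0.0),
            )
            maps = hm.build_all_maps(hm.generate_cohort(cfg, grid), grid)
            scores = traj.score_trials(hm.generate_trajectory_trials(cfg, grid=grid))
            rmse = scores.groupby("subject_id")["rmse_cm"].mean()
            loc = np.array(
                [hm.mean_error_magnitude(maps[(s, 1)]) for s in rmse.index]
            )
            out = traj.motor_vs_localization_correlation(
                rmse.to_numpy(), loc, method="pearson"
            )
            hits += out["r"] > 0.8
        assert hits >= 0.9 * n_cohorts
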