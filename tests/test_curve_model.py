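"""Net-error model, windowed inverse-variance curve fit, derived metrics."""

import numpy as np
import pandas as pd
import pytest

from cevast.curve_model import (
    CurveFitParams,
    NetErrorParams,
    SeverityCurve,
    comparison_points,
    comparison_positions,
    correct_underdispersion,
    estimate_discretization_rmse,
    first5_metric,
    fit_curve,
    label_frames_from_curve,
    net_error,
    tertile_metrics,
)


def _obs(positions, scores, source="mla", pred_error=0.0, spread=0.0):
    n = len(positions)
    return pd.DataFrame(
        {
            "patient_id": ["p0"] * n,
            "position": positions,
            "score": scores,
            "source": [source] * n,
            "pred_error": [pred_error] * n,
            "orientation_spread": [spread] * n,
        }
    )


class TestNetError:
    def test_distance_term_alone(self):
        params = NetErrorParams(disc_rmse=0.0, sys_error=0.0, eps=0.0, disc_for_mla=False)
        assert net_error(0.0, 1.0, params, source="mla", pred_error=0.0) == pytest.approx(0.84)

    def test_expert_quadrature_at_zero_distance(self):
        # sqrt(0.289^2 + 0.1875^2)
        val = net_error(0.3, 0.3, NetErrorParams(), source="expert")
        assert val == pytest.approx(np.sqrt(0.289**2 + 0.1875**2), abs=1e-9)
        assert val == pytest.approx(0.3445, abs=5e-4)

    def test_all_zero_components_hit_floor(self):
        params = NetErrorParams(
            distance_coef=0.0, disc_rmse=0.0, sys_error=0.0, eps=0.01, disc_for_mla=False
        )
        assert net_error(0.5, 0.5, params, source="mla") == 0.01

    def test_mla_blend_of_error_estimates(self):
        params = NetErrorParams(
            distance_coef=0.0, disc_rmse=0.0, frame_err_mix=0.25, disc_for_mla=False
        )
        got = net_error(0.5, 0.5, params, source="mla", pred_error=0.4, orientation_spread=0.8)
        assert got == pytest.approx(0.25 * 0.4 + 0.75 * 0.8)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            net_error(0.1, 0.1, NetErrorParams(frame_err_mix=1.5))


class TestDiscretizationRmse:
    def test_matches_analytic_uniform_rounding_error(self):
        # rounding error is uniform on [-1/2, 1/2] => RMS = sqrt(1/12)
        rmse = estimate_discretization_rmse(n_draws=10**6, seed=0)
        assert rmse == pytest.approx(np.sqrt(1 / 12), abs=0.002)
        assert rmse == pytest.approx(0.289, abs=0.002)

    def test_integer_draws_have_no_discretization_error(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, 1000).astype(float)
        assert np.sqrt(np.mean((x - np.rint(x)) ** 2)) == 0.0

    def test_invalid_draw_count(self):
        with pytest.raises(ValueError):
            estimate_discretization_rmse(n_draws=0)


class TestFitCurve:
    def test_constant_scores_give_constant_curve(self, rng):
        obs = _obs(rng.uniform(0, 1, 300), np.full(300, 2.0))
        curve = fit_curve(obs)
        ok = ~np.isnan(curve.values)
        assert np.allclose(curve.values[ok], 2.0)

    def test_single_observation_window(self):
        obs = _obs([0.5], [1.7])
        curve = fit_curve(obs, grid=np.array([0.5]))
        assert curve.values[0] == pytest.approx(1.7)

    def test_equal_weights_average(self):
        obs = _obs([0.49, 0.51], [1.0, 3.0])
        curve = fit_curve(obs, grid=np.array([0.5]))
        assert curve.values[0] == pytest.approx(2.0)

    def test_empty_windows_are_missing(self):
        obs = _obs([0.0, 0.02], [1.0, 1.0])
        curve = fit_curve(obs)
        far = curve.grid > 0.5
        assert np.all(np.isnan(curve.values[far]))

    def test_all_windows_empty_raises(self):
        obs = _obs([0.5], [1.0])
        with pytest.raises(ValueError):
            fit_curve(obs, grid=np.array([0.0, 1.0]))

    def test_values_within_window_score_range(self, rng):
        obs = _obs(rng.uniform(0, 1, 200), rng.uniform(0, 3, 200))
        params = CurveFitParams()
        curve = fit_curve(obs, params)
        half = params.window / 2
        pos = obs.position.to_numpy()
        sc = obs.score.to_numpy()
        for p0, v in zip(curve.grid, curve.values):
            if np.isnan(v):
                continue
            win = np.abs(pos - p0) <= half + 1e-12
            assert sc[win].min() - 1e-9 <= v <= sc[win].max() + 1e-9

    def test_stderr_shrinks_with_more_observations(self):
        params = NetErrorParams()
        sizes = [2, 8, 32]
        errs = []
        for n in sizes:
            obs = _obs(np.full(n, 0.5), np.full(n, 1.0))
            errs.append(fit_curve(obs, err_params=params, grid=np.array([0.5])).stderr[0])
        assert errs[0] > errs[1] > errs[2]


class TestComparisonPoints:
    def test_grid_spacing_is_one_ninth(self):
        cp = comparison_positions()
        assert len(cp) == 10
        assert np.allclose(np.diff(cp), 1 / 9)

    def test_constant_curve_constant_points(self, rng):
        obs = _obs(rng.uniform(0, 1, 300), np.full(300, 1.2))
        pts = comparison_points(fit_curve(obs))
        assert np.allclose(pts, 1.2)

    def test_window_disjointness(self, rng):
        # perturbing frames inside one point's window moves only that point
        pos = rng.uniform(0, 1, 2000)
        scores = rng.uniform(0.5, 2.0, 2000)
        base = comparison_points(fit_curve(_obs(pos, scores), grid=comparison_positions()))
        p3 = 3 / 9
        inside = np.abs(pos - p3) < 1 / 18 - 1e-9
        assert inside.sum() > 0
        perturbed = scores.copy()
        perturbed[inside] = np.clip(perturbed[inside] + 0.7, 0, 3)
        new = comparison_points(fit_curve(_obs(pos, perturbed), grid=comparison_positions()))
        changed = ~np.isclose(new, base, atol=1e-12)
        assert changed[3]
        assert not np.any(np.delete(changed, 3))


class TestUnderdispersionCorrection:
    def _curve(self, values, stderr):
        grid = comparison_positions()
        return SeverityCurve("p0", "mla", grid, np.asarray(values, float), np.asarray(stderr, float))

    def test_inflation_factor_value(self):
        # s_c = 0.2, mean stderr^2 = 0.15^2 -> f = 0.25 / 0.2 = 1.25
        base = 1.5 + 0.2 * np.array([1, -1] * 5, dtype=float)  # population sd exactly 0.2
        curve = self._curve(base, np.full(10, 0.15))
        out = correct_underdispersion(curve)
        assert out.dispersion_factor == pytest.approx(1.25)
        np.testing.assert_allclose(np.std(out.values), 0.25, atol=1e-12)

    def test_zero_measurement_error_no_change(self):
        base = 1.5 + 0.2 * np.array([1, -1] * 5, dtype=float)
        out = correct_underdispersion(self._curve(base, np.zeros(10)))
        assert out.dispersion_factor == 1.0
        np.testing.assert_array_equal(out.values, base)

    def test_constant_curve_guarded(self):
        out = correct_underdispersion(self._curve(np.full(10, 2.0), np.full(10, 0.3)))
        assert out.dispersion_factor == 1.0
        np.testing.assert_array_equal(out.values, np.full(10, 2.0))

    def test_never_exceeds_scale_bounds(self):
        base = np.array([0.1, 2.9] * 5, dtype=float)
        out = correct_underdispersion(self._curve(base, np.full(10, 1.0)))
        assert np.all((out.values >= 0) & (out.values <= 3))


class TestLabelFromCurve:
    def _curve(self):
        grid = np.array([0.0, 0.5, 1.0])
        return SeverityCurve("p0", "mla", grid, np.array([1.0, 3.0, 2.0]), np.zeros(3))

    def test_grid_point_exact(self):
        assert label_frames_from_curve(self._curve(), [0.5])[0] == 3.0

    def test_midpoint_interpolates(self):
        assert label_frames_from_curve(self._curve(), [0.25])[0] == pytest.approx(2.0)

    def test_extrapolation_clamps(self):
        c = SeverityCurve("p0", "mla", np.array([0.2, 0.8]), np.array([1.0, 2.0]), np.zeros(2))
        assert label_frames_from_curve(c, [0.0])[0] == 1.0
        assert label_frames_from_curve(c, [1.0])[0] == 2.0


class TestMetrics:
    def test_constant_curve_metrics(self):
        grid = np.linspace(0, 1, 200)
        c = SeverityCurve("p0", "mla", grid, np.full(200, 1.5), np.zeros(200))
        m = tertile_metrics(c)
        assert m.first_tertile_mean == m.first_tertile_max == m.si_mean == 1.5

    def test_linear_curve_analytic_values(self):
        grid = np.linspace(0, 1, 2001)
        c = SeverityCurve("p0", "mla", grid, 3 * (1 - grid), np.zeros(grid.size))
        m = tertile_metrics(c)
        assert m.first_tertile_mean == pytest.approx(2.5, abs=0.01)
        assert m.first_tertile_max == pytest.approx(3.0)
        assert m.si_mean == pytest.approx(1.5, abs=0.01)

    def test_single_point_curve(self):
        c = SeverityCurve("p0", "mla", np.array([0.0]), np.array([2.0]), np.array([0.1]))
        m = tertile_metrics(c)
        assert m.first_tertile_mean == m.first_tertile_max == m.si_mean == 2.0

    def test_first5_mean(self):
        obs = _obs([0.01, 0.02, 0.03], [1.0, 2.0, 3.0])
        assert first5_metric(obs) == pytest.approx(2.0)

    def test_first5_missing_when_no_proximal_frames(self):
        obs = _obs([0.5, 0.9], [1.0, 2.0])
        assert np.isnan(first5_metric(obs))

    def test_first5_equals_plain_mean_when_all_proximal(self):
        obs = _obs([0.01, 0.02, 0.04], [0.0, 1.0, 2.0])
        assert first5_metric(obs) == pytest.approx(1.0)
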