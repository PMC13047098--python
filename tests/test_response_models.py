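"""Plateau-model fitting, AIC selection, screening, and the curve battery."""

import math

import numpy as np
import pytest
from scipy import optimize

from helpers import oracle_lp_rss
from aonrvi.response_models import (
    CurveDecision,
    _lp_rss_at,
    aic_least_squares,
    fit_and_screen,
    fit_linear_plateau,
    fit_quadratic_plateau,
    retention_summary,
    screen_and_select,
)
from aonrvi.synthetic_field import plateau_response


class TestLinearPlateau:
    def test_exact_recovery(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        f = fit_linear_plateau(x, 1.0 + 2.0 * np.minimum(x, 3.0))
        assert f.a == pytest.approx(1.0, abs=1e-9)
        assert f.b == pytest.approx(2.0, abs=1e-9)
        assert f.join_x0 == pytest.approx(3.0, abs=1e-9)
        assert f.rss == pytest.approx(0.0, abs=1e-12)
        assert f.plateau_value == pytest.approx(7.0, abs=1e-8)

    def test_flat_response_gives_zero_slope(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        f = fit_linear_plateau(x, np.full(5, 3.0))
        assert f.b == pytest.approx(0.0, abs=1e-9)

    def test_unbent_line_drives_join_to_boundary(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        f = fit_linear_plateau(x, 2.0 * x)
        assert f.join_x0 == pytest.approx(4.0, abs=1e-9)
        assert f.rss == pytest.approx(0.0, abs=1e-12)

    def test_input_contract(self):
        with pytest.raises(ValueError):
            fit_linear_plateau([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # < 4 obs
        with pytest.raises(ValueError):
            fit_linear_plateau([1.0, 1.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])

    def test_matches_profiling_oracle_on_random_data(self):
        rng = np.random.default_rng(101)
        for _ in range(40):
            x = np.sort(rng.uniform(0, 300, 5))
            if len(np.unique(x)) < 3:
                continue
            y = rng.normal(8, 2, 5)
            fit = fit_linear_plateau(x, y)
            ro = oracle_lp_rss(x, y)
            assert abs(fit.rss - ro) <= 1e-8 * max(ro, 1e-12)


class TestQuadraticPlateau:
    def test_exact_recovery_with_vertex_arithmetic(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.where(x < 2.0, 4.0 * x - x**2, 4.0)
        f = fit_quadratic_plateau(x, y)
        assert f.b == pytest.approx(4.0, abs=1e-8)
        assert f.c == pytest.approx(-1.0, abs=1e-8)
        assert f.join_x0 == pytest.approx(2.0, abs=1e-8)  # -b/(2c)
        assert f.plateau_value == pytest.approx(4.0, abs=1e-8)
        assert f.rss == pytest.approx(0.0, abs=1e-12)

    def test_convex_data_screened_not_concave_down(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        f = fit_quadratic_plateau(x, x**2)
        assert f.c > 0
        d = screen_and_select(fit_linear_plateau(x, x**2), f, max_n_rate=4.0)
        assert "not_concave_down" in d.qp_reasons

    def test_prediction_continuous_and_smooth_at_join(self):
        x = np.array([0.0, 50.0, 120.0, 200.0, 280.0])
        y = plateau_response(x, "quadratic_plateau", 6.0, 12.0, 170.0)
        f = fit_quadratic_plateau(x, y)
        eps = 1e-6
        left = f.predict(f.join_x0 - eps)
        right = f.predict(f.join_x0 + eps)
        assert left == pytest.approx(right, abs=1e-9)
        dleft = (f.predict(f.join_x0) - f.predict(f.join_x0 - eps)) / eps
        assert dleft == pytest.approx(0.0, abs=1e-4)  # slope -> 0 at vertex

    def test_zero_noise_transect_recovery(self):
        rates = np.array([44.0, 89.0, 155.0, 222.0, 289.0])
        rng = np.random.default_rng(55)
        for _ in range(25):
            join = rng.uniform(100.0, 270.0)
            y = plateau_response(rates, "quadratic_plateau", 7.0, 13.0, join)
            f = fit_quadratic_plateau(rates, y)
            assert f.join_x0 == pytest.approx(join, abs=0.5)


class TestAIC:
    def test_stated_formula(self):
        assert aic_least_squares(5.0, 5, 3) == pytest.approx(8.0)

    def test_rss_ratio_e_gives_difference_n(self):
        a1 = aic_least_squares(2.0, 5, 3)
        a2 = aic_least_squares(2.0 * math.e, 5, 3)
        assert a2 - a1 == pytest.approx(5.0)

    def test_perfect_fit_is_minus_infinity(self):
        assert aic_least_squares(0.0, 5, 3) == -math.inf

    def test_negative_rss_rejected(self):
        with pytest.raises(ValueError):
            aic_least_squares(-1.0, 5, 3)


class TestScreenAndSelect:
    @staticmethod
    def fits_for(y_fn, x=None):
        x = np.array([0.0, 70.0, 140.0, 210.0, 280.0]) if x is None else x
        y = y_fn(x)
        return x, fit_linear_plateau(x, y), fit_quadratic_plateau(x, y)

    def test_low_r2_eliminates(self):
        rng = np.random.default_rng(2)
        x = np.array([0.0, 70.0, 140.0, 210.0, 280.0])
        y = rng.normal(0, 1, 5)  # pure noise: both fits weak sooner or later
        lp, qp = fit_linear_plateau(x, y), fit_quadratic_plateau(x, y)
        d = screen_and_select(lp, qp, max_n_rate=280.0)
        if lp.r_squared <= 0.5:
            assert "low_r2" in d.lp_reasons

    def test_flat_response_fails_positive_slope(self):
        x, lp, qp = self.fits_for(lambda x: np.full_like(x, 5.0))
        d = screen_and_select(lp, qp, max_n_rate=280.0)
        assert "nonpositive_slope" in d.lp_reasons
        assert d.selected is None

    def test_lower_aic_wins(self):
        x = np.array([0.0, 70.0, 140.0, 210.0, 280.0])
        y = plateau_response(x, "linear_plateau", 5.0, 12.0, 180.0)
        y = y + np.array([0.01, -0.01, 0.02, -0.01, 0.0])
        lp, qp = fit_linear_plateau(x, y), fit_quadratic_plateau(x, y)
        d = screen_and_select(lp, qp, max_n_rate=280.0)
        if not d.lp_reasons and not d.qp_reasons:
            expected = "linear_plateau" if lp.aic < qp.aic else "quadratic_plateau"
            if abs(lp.aic - qp.aic) >= 1e-9:
                assert d.selected == expected

    def test_exact_tie_prefers_quadratic(self):
        # both families fit a 2-point rise + plateau exactly -> AIC tie
        x = np.array([0.0, 100.0, 200.0, 250.0, 300.0])
        y = plateau_response(x, "quadratic_plateau", 5.0, 12.0, 150.0)
        lp, qp = fit_linear_plateau(x, y), fit_quadratic_plateau(x, y)
        if lp.rss < 1e-12 and qp.rss < 1e-12:
            d = screen_and_select(lp, qp, max_n_rate=300.0)
            assert d.selected == "quadratic_plateau"

    def test_join_beyond_max_rate_discarded(self):
        x = np.array([0.0, 70.0, 140.0, 210.0, 280.0])
        # rising quadratic with vertex past the tested range
        y = plateau_response(x, "quadratic_plateau", 5.0, 14.0, 400.0)
        lp, qp = fit_linear_plateau(x, y), fit_quadratic_plateau(x, y)
        d = screen_and_select(lp, qp, max_n_rate=280.0)
        if d.selected == "quadratic_plateau":
            assert d.discarded_exceeds_max
            assert d.aonr is None

    def test_join_at_max_rate_allowed(self):
        x = np.array([0.0, 70.0, 140.0, 210.0, 280.0])
        f = fit_linear_plateau(x, 2.0 * x)
        d = screen_and_select(f, fit_quadratic_plateau(x, 2.0 * x),
                              max_n_rate=280.0)
        if d.selected == "linear_plateau":
            assert d.aonr == pytest.approx(280.0, abs=1e-6)
            assert not d.discarded_exceeds_max

    def test_failed_screen_never_selected_regardless_of_aic(self):
        # a *decreasing* plateau curve: the linear-plateau fits it perfectly
        # (AIC -inf) but has a negative slope, so it must never be selected
        x = np.array([0.0, 70.0, 140.0, 210.0, 280.0])
        y = 12.0 - 2.0 * np.minimum(x, 140.0) / 140.0
        lp, qp = fit_linear_plateau(x, y), fit_quadratic_plateau(x, y)
        assert lp.rss == pytest.approx(0.0, abs=1e-12)
        assert lp.b < 0
        d = screen_and_select(lp, qp, max_n_rate=280.0)
        assert "nonpositive_slope" in d.lp_reasons
        assert d.selected != "linear_plateau"


class TestCurveBattery:
    def test_enumeration_and_retention_reaggregation(self, mini_config,
                                                     tmp_path):
        from aonrvi.pipeline import default_run_config, run_all

        cfg = default_run_config(seed=5)
        cfg.sim = mini_config
        cfg.write_scenes = False
        tables = run_all(cfg, tmp_path / "run")
        dec = tables["decisions"]
        vi_dec = dec[dec.vi_name != "yield"]
        n_transects = len(mini_config.trials) * mini_config.transects_per_trial
        assert len(vi_dec) == n_transects * 3 * 16
        assert (dec.vi_name == "yield").sum() == n_transects
        # retention over any partition reaggregates to the overall percentage
        overall = retention_summary(vi_dec)["pct_usable"].iloc[0]
        by_field = retention_summary(vi_dec, by=("trial_id",))
        recombined = (
            100.0 * by_field["n_usable"].sum() / by_field["n_curves"].sum()
        )
        assert recombined == pytest.approx(overall)
        by_vi = retention_summary(vi_dec, by=("vi_name", "timing"))
        assert by_vi["n_curves"].sum() == len(vi_dec)
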