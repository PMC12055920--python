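"""Feature extraction: closed forms vs numeric oracles, symmetries, filters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from rptlab.curve_fits import CurveFit, FitQuality, fit_powerlaw, fit_quadratic
from rptlab.features import (FEATURE_NAMES, OutlierPolicy,
                             feature_outlier_filter, limit_features,
                             tradeoff_features, value_features)

Q = FitQuality(1.0, 1.0, math.inf, 0.0)


def mkfit(family, params):
    return CurveFit(family, tuple(params), Q, 6)


# fits built from published group parameters, used as realistic inputs
PL_PLUS = mkfit("powerlaw", (0.440, 0.296))
PL_MINUS = mkfit("powerlaw", (0.473, 0.274))
LOG_PLUS = mkfit("logarithmic", (2.210, 2.047))
LOG_MINUS = mkfit("logarithmic", (2.330, 1.932))
QUAD_PLUS = mkfit("quadratic", (-0.476, 1.468, 0.067))
QUAD_MINUS = mkfit("quadratic", (-0.553, 1.667, 0.065))


class TestValueFeatures:
    def test_worked_values(self):
        out = value_features(PL_PLUS, PL_MINUS, LOG_PLUS, LOG_MINUS)
        assert out["LA"] == pytest.approx(0.473 / 0.440, abs=1e-9)  # 1.075
        assert out["RA"] == pytest.approx(0.37333, abs=1e-4)
        assert out["LR"] == pytest.approx((1 - 0.473) / 1.5, abs=1e-9)
        assert out["beta_plus"] == pytest.approx(0.11851, abs=1e-4)
        assert out["beta_minus"] < 0

    def test_ra_matches_numeric_derivative_oracle(self):
        h = lambda k: 0.296 * k**0.440
        eps = 1e-4
        d1 = (h(1.5 + eps) - h(1.5 - eps)) / (2 * eps)
        d2 = (h(1.5 + eps) - 2 * h(1.5) + h(1.5 - eps)) / eps**2
        out = value_features(PL_PLUS, PL_MINUS, LOG_PLUS, LOG_MINUS)
        assert out["RA"] == pytest.approx(abs(d2 / d1), abs=1e-6)

    def test_beta_matches_rootfind_oracle(self):
        root = optimize.brentq(lambda k: 2.210 * np.log10(k) + 2.047, 1e-6, 10.0)
        out = value_features(PL_PLUS, PL_MINUS, LOG_PLUS, LOG_MINUS)
        assert out["beta_plus"] == pytest.approx(root, abs=1e-9)
        root_m = optimize.brentq(lambda k: 2.330 * np.log10(k) + 1.932, 1e-6, 10.0)
        assert out["beta_minus"] == pytest.approx(-root_m, abs=1e-9)

    def test_symmetric_fits_give_unit_loss_aversion(self):
        out = value_features(PL_PLUS, PL_PLUS, LOG_PLUS, LOG_PLUS)
        assert out["LA"] == 1.0
        assert out["beta_plus"] == pytest.approx(-out["beta_minus"])

    def test_missing_fits_yield_nan(self):
        invalid = CurveFit("powerlaw", (math.nan, math.nan), Q, 2, valid=False)
        out = value_features(invalid, PL_MINUS, None, LOG_MINUS)
        assert math.isnan(out["LA"]) and math.isnan(out["RA"])
        assert math.isnan(out["beta_plus"]) and not math.isnan(out["beta_minus"])

    def test_logarithmic_ra_variant_is_constant_one_over_k(self):
        out = value_features(PL_PLUS, PL_MINUS, LOG_PLUS, LOG_MINUS,
                             ra_family="logarithmic")
        assert out["RA"] == pytest.approx(1.0 / 1.5)


class TestLimitFeatures:
    def test_worked_vertex_and_area_values(self):
        out = limit_features(QUAD_PLUS, QUAD_MINUS)
        assert out["rho_plus"] == pytest.approx(1.5420, abs=1e-4)
        assert out["alpha_plus"] == pytest.approx(1.1988, abs=1e-4)
        assert out["q_plus"] == pytest.approx(2.535, abs=1e-3)

    def test_vertex_matches_grid_argmax_oracle(self):
        k = np.linspace(0.0, 4.0, 400001)
        sigma = -0.476 * k**2 + 1.468 * k + 0.067
        out = limit_features(QUAD_PLUS, QUAD_MINUS)
        assert out["rho_plus"] == pytest.approx(k[np.argmax(sigma)], abs=1e-5)
        assert out["alpha_plus"] == pytest.approx(sigma.max(), abs=1e-6)

    def test_area_matches_numerical_integration_oracle(self):
        f = lambda k: -0.476 * k**2 + 1.468 * k + 0.067
        hi = optimize.brentq(f, 2.0, 5.0)
        oracle, _ = integrate.quad(f, 0.0, hi)
        out = limit_features(QUAD_PLUS, QUAD_MINUS)
        assert out["q_plus"] == pytest.approx(oracle, abs=1e-6)

    def test_unit_parabola_hand_integral(self):
        fit = mkfit("quadratic", (-1.0, 0.0, 1.0))
        out = limit_features(fit, fit)
        assert out["rho_plus"] == 0.0
        assert out["alpha_plus"] == 1.0
        assert out["q_plus"] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_convex_fit_gives_missing_features(self):
        convex = mkfit("quadratic", (0.5, 0.1, 0.1))
        out = limit_features(convex, QUAD_MINUS)
        assert math.isnan(out["rho_plus"]) and math.isnan(out["q_plus"])
        assert not math.isnan(out["rho_minus"])

    def test_parabola_below_axis_has_zero_area(self):
        below = mkfit("quadratic", (-1.0, 0.0, -0.5))
        assert limit_features(below, below)["q_plus"] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_random_admissible_fits_vs_oracles(self, seed):
        rng = np.random.default_rng(seed)
        a = -rng.uniform(0.2, 1.0)
        b = rng.uniform(0.8, 2.0)
        c = rng.uniform(0.0, 0.3)
        fit = mkfit("quadratic", (a, b, c))
        out = limit_features(fit, fit)
        k = np.linspace(0, 6, 600001)
        s = a * k**2 + b * k + c
        assert out["rho_plus"] == pytest.approx(k[np.argmax(s)], abs=1e-4)
        assert out["alpha_plus"] == pytest.approx(s.max(), abs=1e-6)
        f = lambda x: a * x**2 + b * x + c
        hi = optimize.brentq(f, out["rho_plus"], 20.0)
        oracle, _ = integrate.quad(f, 0.0, hi)
        assert out["q_plus"] == pytest.approx(oracle, abs=1e-6)


class TestTradeoffFeatures:
    def test_single_point(self):
        out = tradeoff_features([(1.0, 1.0)])
        assert out["theta"] == pytest.approx(45.0)
        assert out["sigma_theta"] == 0.0
        assert out["r"] == pytest.approx(math.sqrt(2))
        assert out["sigma_r"] == 0.0

    def test_axis_points(self):
        out = tradeoff_features([(3.0, 0.0), (0.0, 3.0)])
        assert out["theta"] == pytest.approx(45.0)  # mean of 0 and 90
        assert out["r"] == pytest.approx(3.0)
        assert out["sigma_r"] == pytest.approx(0.0, abs=1e-12)

    def test_approach_weighted_pattern_exceeds_45_degrees(self):
        out = tradeoff_features([(1.0, 2.0), (0.5, 2.5), (1.5, 2.0)])
        assert out["theta"] > 45.0

    def test_origin_points_excluded_from_angles_counted_in_radii(self):
        out = tradeoff_features([(0.0, 0.0), (1.0, 1.0)])
        assert out["theta"] == pytest.approx(45.0)
        assert out["r"] == pytest.approx(math.sqrt(2) / 2)

    def test_all_origin_points(self):
        out = tradeoff_features([(0.0, 0.0), (0.0, 0.0)])
        assert math.isnan(out["theta"]) and out["r"] == 0.0

    def test_invariant_to_category_order(self):
        pts = [(0.5, 2.0), (1.5, 1.0), (2.0, 2.5), (0.1, 0.7)]
        a = tradeoff_features(pts)
        b = tradeoff_features(pts[::-1])
        for k in ("theta", "sigma_theta", "r", "sigma_r"):
            assert a[k] == pytest.approx(b[k], abs=1e-12)


class TestSignSymmetry:
    def test_mirrored_ratings_swap_paired_features(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.2, 2.8, 6)
        h = 0.3 * x**0.5 * 10 ** rng.normal(0, 0.02, 6)
        s = -0.4 * x**2 + 1.3 * x + 0.1 + rng.normal(0, 0.01, 6)
        pl = fit_powerlaw(list(zip(x, h)))
        qd = fit_quadratic(list(zip(x, s)))
        # mirrored data: approach and avoidance fits exchange roles
        fwd = value_features(pl, PL_MINUS, LOG_PLUS, LOG_MINUS)
        rev = value_features(PL_MINUS, pl, LOG_MINUS, LOG_PLUS)
        assert fwd["LA"] == pytest.approx(1.0 / rev["LA"])
        assert fwd["RA"] == pytest.approx(rev["LR"])
        assert fwd["beta_plus"] == pytest.approx(-rev["beta_minus"])
        lf_fwd = limit_features(qd, QUAD_MINUS)
        lf_rev = limit_features(QUAD_MINUS, qd)
        assert lf_fwd["rho_plus"] == pytest.approx(lf_rev["rho_minus"])
        assert lf_fwd["alpha_plus"] == pytest.approx(lf_rev["alpha_minus"])
        assert lf_fwd["q_plus"] == pytest.approx(lf_rev["q_minus"])


class TestOutlierFilter:
    def _table(self, **overrides):
        base = {name: [0.5, 0.6, 0.55] for name in FEATURE_NAMES}
        base["participant_id"] = ["a", "b", "c"]
        df = pd.DataFrame(base)
        for col, vals in overrides.items():
            df[col] = vals
        return df

    def test_threshold_mode_la(self):
        table = self._table(LA=[250.0, 0.9, 1.0])
        kept, log = feature_outlier_filter(table, OutlierPolicy(mode="threshold"))
        assert list(kept["participant_id"]) == ["b", "c"]
        assert log.iloc[0]["reasons"] == "LA"

    def test_threshold_mode_q_plus(self):
        table = self._table(q_plus=[2.0, 150.0, 2.5])
        kept, log = feature_outlier_filter(table, OutlierPolicy(mode="threshold"))
        assert list(kept["participant_id"]) == ["a", "c"]
        assert "q_plus" in log.iloc[0]["reasons"]

    def test_median_values_retained_under_both_modes(self):
        table = self._table()
        for mode in ("threshold", "iqr"):
            kept, log = feature_outlier_filter(table, OutlierPolicy(mode=mode))
            assert len(kept) == 3 and len(log) == 0

    def test_iqr_mode_excludes_extreme(self):
        la = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 60.0]
        base = {name: [0.5] * 7 for name in FEATURE_NAMES}
        base["participant_id"] = list("abcdefg")
        table = pd.DataFrame(base)
        table["LA"] = la
        kept, log = feature_outlier_filter(table, OutlierPolicy(mode="iqr"))
        assert "g" not in set(kept["participant_id"])
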