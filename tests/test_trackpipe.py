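"""Track pipeline: geometry, wind fit, angle imputation, trend model."""

import math

import numpy as np
import pandas as pd
import pytest

from soartrade.trackpipe import (
    PipelineConfig,
    Track,
    TrackSegment,
    air_relative_yaw,
    estimate_gamma,
    estimate_wind,
    fit_trend,
    fit_wind_sinusoid,
    ground_velocity,
    project_track,
    segment_metrics,
)


class TestProjection:
    def test_centroid_maps_to_origin(self):
        tr = project_track("a", [0, 1, 2], lat=[10.0, 10.001, 10.002],
                           lon=[20.0, 20.0, 20.0])
        assert tr.x[1] == pytest.approx(0.0, abs=1e-9)
        assert tr.y[1] == pytest.approx(0.0, abs=1e-9)

    def test_north_step_scale(self):
        tr = project_track("a", [0, 1], lat=[0.0, 0.001], lon=[0.0, 0.0])
        assert tr.y[1] - tr.y[0] == pytest.approx(111.19, abs=0.05)
        assert tr.x[1] - tr.x[0] == pytest.approx(0.0, abs=1e-9)

    def test_preprojected_passthrough(self):
        x = np.array([0.0, 5.0])
        y = np.array([1.0, 2.0])
        tr = project_track("a", [0, 1], x=x, y=y)
        assert np.array_equal(tr.x, x) and np.array_equal(tr.y, y)

    def test_latitude_range_check(self):
        with pytest.raises(ValueError):
            project_track("a", [0, 1], lat=[95.0, 95.0], lon=[0.0, 0.0])

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            Track("a", np.array([0.0, 0.0]), np.zeros(2), np.zeros(2))


class TestGroundVelocity:
    def test_three_four_five_triangle(self):
        v = ground_velocity(np.array([0.0, 1.0]), np.array([0.0, 3.0]),
                            np.array([0.0, 4.0]))
        assert v.Vh.iloc[0] == pytest.approx(5.0)
        assert v.thetaV.iloc[0] == pytest.approx(math.degrees(math.atan2(3, 4)))

    def test_due_south_bearing(self):
        v = ground_velocity(np.array([0.0, 1.0]), np.array([0.0, 0.0]),
                            np.array([0.0, -7.0]))
        assert v.thetaV.iloc[0] == pytest.approx(180.0)

    def test_stationary_sample_dropped(self):
        v = ground_velocity(np.array([0.0, 1.0, 2.0]),
                            np.array([0.0, 0.0, 3.0]),
                            np.array([0.0, 0.0, 4.0]))
        assert len(v) == 1

    def test_nonuniform_dt_used(self):
        v = ground_velocity(np.array([0.0, 2.0]), np.array([0.0, 6.0]),
                            np.array([0.0, 8.0]))
        assert v.Vh.iloc[0] == pytest.approx(5.0)


class TestWindSinusoidFit:
    def test_exact_recovery_noiseless(self):
        th = np.arange(0.0, 360.0, 10.0)
        vh = 10.0 + 3.0 * np.sin(np.radians(th)) + 4.0 * np.cos(np.radians(th))
        vbar, a, b, rms = fit_wind_sinusoid(vh, th)
        assert (vbar, a, b) == pytest.approx((10.0, 3.0, 4.0), abs=1e-12)
        assert rms <= 1e-12

    def test_noisy_recovery_within_sampling_error(self):
        rng = np.random.default_rng(11)
        th = rng.uniform(0, 360, 300)
        vh = 10.0 + 3.0 * np.sin(np.radians(th)) + 4.0 * np.cos(np.radians(th))
        vh = vh + rng.normal(0, 0.1, th.size)
        vbar, a, b, _ = fit_wind_sinusoid(vh, th)
        se = 0.1 / math.sqrt(th.size / 2)   # ~ OLS coefficient SE
        assert abs(a - 3.0) < 3 * se and abs(b - 4.0) < 3 * se

    def test_rank_deficient_rejected(self):
        th = np.full(200, 45.0)
        with pytest.raises(ValueError):
            fit_wind_sinusoid(np.full(200, 5.0), th)


def _segment_from(vh, theta_v, individual="b", t0=0.0):
    n = len(vh)
    df = pd.DataFrame({"t": np.arange(n, dtype=float),
                       "Vx": vh * np.sin(np.radians(theta_v)),
                       "Vy": vh * np.cos(np.radians(theta_v)),
                       "Vh": vh, "thetaV": theta_v})
    return TrackSegment(individual, t0, df)


class TestEstimateWind:
    def test_closed_form_amplitude_and_direction(self):
        th = np.linspace(0.0, 359.0, 300)
        vh = 12.0 + 3.0 * np.sin(np.radians(th)) + 4.0 * np.cos(np.radians(th))
        est = estimate_wind(_segment_from(vh, th))
        assert est.valid
        assert est.W_0 == pytest.approx(5.0, abs=1e-9)
        assert est.W_ref == pytest.approx(1.80 * 5.0 - 1.42, abs=1e-9)
        assert est.sigma_bar == pytest.approx(7.58 / 9.97, abs=1e-9)
        assert est.theta_W_deg == pytest.approx(math.degrees(math.atan2(3, 4)))

    def test_amplitude_equals_half_peak_to_trough_of_fit(self):
        th = np.linspace(0.0, 359.0, 720)
        rng = np.random.default_rng(2)
        vh = 11.0 + 2.0 * np.sin(np.radians(th)) - 1.5 * np.cos(np.radians(th))
        est = estimate_wind(_segment_from(vh + rng.normal(0, 0.2, th.size), th))
        grid = np.arange(0.0, 360.0, 0.1)
        fitted = est.V_h_bar + est.a * np.sin(np.radians(grid)) \
            + est.b * np.cos(np.radians(grid))
        assert est.W_0 == pytest.approx((fitted.max() - fitted.min()) / 2,
                                        abs=1e-6)

    def test_north_peak_means_northward_tailwind(self):
        th = np.linspace(0.0, 359.0, 300)
        vh = 12.0 + 1.0 * np.cos(np.radians(th))   # a=0, b=1: peak at 0 deg
        est = estimate_wind(_segment_from(vh, th))
        circ = min(est.theta_W_deg, 360.0 - est.theta_W_deg)
        assert circ == pytest.approx(0.0, abs=1e-6)

    def test_weak_wind_segment_discarded(self):
        th = np.linspace(0.0, 359.0, 300)
        vh = 12.0 + 0.5 * np.cos(np.radians(th))   # W_0 = 0.5 -> W_ref < 0
        est = estimate_wind(_segment_from(vh, th))
        assert not est.valid
        assert "non-positive" in est.reject_reason

    def test_quality_gates(self):
        cfg = PipelineConfig()
        th = np.linspace(0.0, 359.0, 40)
        vh = 12.0 + 4.0 * np.cos(np.radians(th))
        est = estimate_wind(_segment_from(vh, th), cfg)
        assert not est.valid and "too few samples" in est.reject_reason
        th2 = np.linspace(0.0, 45.0, 200)
        est2 = estimate_wind(_segment_from(12 + 4 * np.cos(np.radians(th2)),
                                           th2), cfg)
        assert not est2.valid and "span" in est2.reject_reason


class TestAirRelativeYaw:
    def test_collinear_wind(self):
        psi, uh, clamped = air_relative_yaw(12.0, 50.0, 5.0, 50.0)
        assert uh == pytest.approx(7.0)
        assert psi == pytest.approx(0.0, abs=1e-12)

    def test_opposed_wind(self):
        psi, uh, _ = air_relative_yaw(3.0, 180.0, 4.0, 0.0)
        assert uh == pytest.approx(7.0)
        assert psi == pytest.approx(0.0, abs=1e-10)

    def test_perpendicular_wind_right_triangle(self):
        psi, uh, _ = air_relative_yaw(3.0, 90.0, 4.0, 0.0)
        assert uh == pytest.approx(5.0)
        assert psi == pytest.approx(math.degrees(math.asin(3 / 5)))

    def test_principal_branch_bounds(self):
        rng = np.random.default_rng(5)
        psi, _, _ = air_relative_yaw(rng.uniform(1, 25, 500),
                                     rng.uniform(0, 360, 500),
                                     8.0, 123.0)
        assert np.nanmin(psi) >= -90.0 and np.nanmax(psi) <= 90.0

    def test_degenerate_zero_airspeed(self):
        psi, uh, _ = air_relative_yaw(5.0, 30.0, 5.0, 30.0)
        assert uh == pytest.approx(0.0)
        assert np.isnan(psi)


class TestGammaImputation:
    def test_hand_values(self):
        assert estimate_gamma(10.0, 90.0) == pytest.approx(3.0667, abs=1e-4)
        assert estimate_gamma(0.0, 110.0) == pytest.approx(0.0003, abs=1e-6)

    def test_slope_increases_with_theta(self):
        g60 = estimate_gamma(10.0, 60.0) - estimate_gamma(0.0, 60.0)
        g120 = estimate_gamma(10.0, 120.0) - estimate_gamma(0.0, 120.0)
        assert g120 > g60

    def test_radian_variant(self):
        out = estimate_gamma(10.0, 90.0, units="rad")
        ell = 0.00309 * 90 + 0.02
        m = math.radians(0.00427 * 90 - 0.47)
        assert out == pytest.approx(ell * math.radians(10.0) - m)
        with pytest.raises(ValueError):
            estimate_gamma(1.0, 90.0, units="grad")


class TestSegmentMetrics:
    def test_hand_computed_means(self):
        # 10 samples with known geometry; oracle computed sample by sample
        cfg = PipelineConfig(min_valid_samples=1)
        theta_w = 0.0
        W = 8.0
        theta_v = np.array([60, 70, 80, 90, 100, 110, 120, 65, 75, 85],
                           dtype=float)
        vh = np.full(10, 14.0)
        seg = _segment_from(vh, theta_v)
        from soartrade.trackpipe import WindEstimate
        wind = WindEstimate(V_h_bar=14.0, a=0.0, b=W, W_0=W,
                            W_ref=1.8 * W - 1.42, theta_W_deg=theta_w,
                            sigma_bar=(1.8 * W - 1.42) / 9.97,
                            residual_rms=0.0, n=10)
        m = segment_metrics(seg, wind, cfg, min_retained=1)
        # oracle: explicit loops over the ten samples
        etas, epss = [], []
        for tv in theta_v:
            d = math.radians(tv - theta_w)
            uh = math.sqrt(14 ** 2 + wind.W_ref ** 2
                           - 2 * 14 * wind.W_ref * math.cos(d))
            psi = math.degrees(math.asin(14 / uh * math.sin(d)))
            th = abs(tv - theta_w)
            gam = (0.00309 * th + 0.02) * psi - (0.00427 * th - 0.47)
            etas.append(math.sin(2 * math.radians(gam))
                        * math.sin(math.radians(psi)))
            epss.append(math.cos(math.radians(gam))
                        * math.sin(math.radians(psi + th)))
        assert m.eta_bar == pytest.approx(np.mean(etas), abs=1e-12)
        assert m.epsilon_bar == pytest.approx(np.mean(epss), abs=1e-12)
        assert m.n_retained == 10

    def test_constant_extremes(self):
        # synthetic psi/gamma giving eta exactly 1 requires gamma=45, psi=90;
        # exercised through the coefficient formulas directly in dynamics
        # tests; here check the crosswind filter drops out-of-band samples
        cfg = PipelineConfig(min_valid_samples=1)
        theta_v = np.array([10.0, 30.0, 90.0, 100.0, 170.0])
        vh = np.full(5, 14.0)
        from soartrade.trackpipe import WindEstimate
        wind = WindEstimate(V_h_bar=14.0, a=0.0, b=8.0, W_0=8.0,
                            W_ref=1.8 * 8 - 1.42, theta_W_deg=0.0,
                            sigma_bar=1.0, residual_rms=0.0, n=5)
        m = segment_metrics(_segment_from(vh, theta_v), wind, cfg,
                            min_retained=1)
        assert m.n_retained == 2           # only 90 and 100 in [60, 120]
        assert 60.0 <= m.mean_theta_deg <= 120.0

    def test_too_few_retained_rejects(self):
        cfg = PipelineConfig()
        theta_v = np.full(200, 30.0) + np.arange(200) * 0.01  # outside band
        vh = np.full(200, 12.0)
        from soartrade.trackpipe import WindEstimate
        wind = WindEstimate(V_h_bar=12.0, a=0.0, b=6.0, W_0=6.0,
                            W_ref=9.38, theta_W_deg=0.0, sigma_bar=0.94,
                            residual_rms=0.0, n=200)
        assert segment_metrics(_segment_from(vh, theta_v), wind, cfg) is None


class TestTrendFit:
    @staticmethod
    def _table(rng, slope, n_ind=4, n_per=30, intercept_sd=0.05, noise=0.02):
        rows = []
        for k in range(n_ind):
            b0 = 0.5 + rng.normal(0, intercept_sd)
            sig = rng.uniform(0.7, 2.0, n_per)
            y = b0 + slope * sig + rng.normal(0, noise, n_per)
            rows.append(pd.DataFrame({"id": f"i{k}", "sigma_bar": sig,
                                      "eta_bar": y}))
        return pd.concat(rows, ignore_index=True)

    def test_recovers_known_slope(self):
        rng = np.random.default_rng(21)
        table = self._table(rng, slope=-0.8)
        fit = fit_trend(table, "eta_bar")
        assert fit.slope == pytest.approx(-0.8, abs=3 * fit.slope_se)
        assert fit.p_value < 0.001
        assert fit.n_individuals == 4

    def test_constant_response_slope_zero(self):
        d = pd.DataFrame({"id": ["a"] * 10 + ["b"] * 10,
                          "sigma_bar": np.tile(np.linspace(0.8, 2, 10), 2),
                          "eta_bar": np.full(20, 0.4)})
        fit = fit_trend(d, "eta_bar")
        assert fit.slope == 0.0

    def test_sign_flip_is_exact(self):
        rng = np.random.default_rng(33)
        table = self._table(rng, slope=-0.6)
        flipped = table.assign(eta_bar=-table.eta_bar)
        f1 = fit_trend(table, "eta_bar")
        f2 = fit_trend(flipped, "eta_bar")
        assert f1.slope == pytest.approx(-f2.slope, rel=1e-9)

    def test_single_individual_falls_back_to_pooled(self):
        rng = np.random.default_rng(4)
        table = self._table(rng, slope=-0.5, n_ind=1)
        fit = fit_trend(table, "eta_bar")
        assert fit.model == "pooled-ols"

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(pd.DataFrame(), "vnet")
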