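"""Track feature vector, autocorrelations, covariance diffusion estimator."""

import numpy as np
import pytest

from conftest import DT, make_track

from thermotrack import features as ft
from thermotrack import synthetic
from thermotrack.physics import brownian_D_um2_s


def straight_track(n=20, speed=15.0, dt=DT, heading=0.0):
    step = speed * dt * np.array([np.cos(heading), np.sin(heading)])
    return make_track(np.arange(n)[:, None] * step, dt=dt)


class TestMeanSpeed:
    def test_hand_computed_value(self):
        # steps of 5 um at 15 fps -> 75 um/s
        tr = make_track([(0, 0), (3, 4), (6, 8)], dt=1 / 15)
        assert ft.mean_speed(tr) == pytest.approx(75.0)

    def test_stationary_track_zero(self):
        tr = make_track(np.zeros((10, 2)))
        assert ft.mean_speed(tr) == 0.0

    def test_constant_velocity_exact(self):
        assert ft.mean_speed(straight_track(speed=23.0)) == pytest.approx(23.0)

    def test_rigid_motion_invariance(self, rng):
        pos = rng.normal(size=(30, 2)) * 5
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = pos @ R.T + rng.normal(size=2) * 100
        assert ft.mean_speed(make_track(moved)) == \
            pytest.approx(ft.mean_speed(make_track(pos)), rel=1e-9)


class TestMeanAcceleration:
    def test_constant_velocity_zero(self):
        assert ft.mean_acceleration(straight_track()) == pytest.approx(0.0, abs=1e-9)

    def test_speed_change_hand_value(self):
        # speeds 10 then 20 um/s along one axis, dt = 0.1 s -> 100 um/s^2
        tr = make_track([(0, 0), (1.0, 0), (3.0, 0)], dt=0.1)
        assert ft.mean_acceleration(tr) == pytest.approx(100.0)

    def test_right_angle_turn_value(self):
        # constant speed s with one 90-degree turn: |dv| = s*sqrt(2)
        s, dt = 10.0, 0.1
        tr = make_track([(0, 0), (s * dt, 0), (s * dt, s * dt)], dt=dt)
        assert ft.mean_acceleration(tr) == pytest.approx(s * np.sqrt(2) / dt)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ft.mean_acceleration(make_track([(0, 0), (1, 1)]))


class TestNetDisplacement:
    def test_straight_track_ratio_one(self):
        disp, rate, ratio = ft.net_displacement(straight_track(n=20, speed=15.0))
        assert ratio == pytest.approx(1.0)
        assert rate == pytest.approx(15.0)
        assert disp == pytest.approx(15.0 * 19 * DT)

    def test_closed_square_ratio_zero(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
        disp, rate, ratio = ft.net_displacement(make_track(square))
        assert disp == 0.0 and rate == 0.0 and ratio == 0.0

    def test_ratio_never_exceeds_one(self, rng):
        # chord <= path for any polyline
        for _ in range(25):
            pos = rng.normal(size=(rng.integers(3, 40), 2)) * 10
            _, _, ratio = ft.net_displacement(make_track(pos))
            assert ratio <= 1.0 + 1e-9


class TestSinuosity:
    def test_straight_path_is_one(self):
        val, capped = ft.sinuosity(straight_track())
        assert val == pytest.approx(1.0) and not capped

    def test_semicircle_is_half_pi(self):
        theta = np.linspace(0, np.pi, 200)
        arc = np.column_stack([np.cos(theta), np.sin(theta)]) * 5
        val, _ = ft.sinuosity(make_track(arc))
        assert val == pytest.approx(np.pi / 2, rel=1e-3)

    def test_closed_loop_capped(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
        val, capped = ft.sinuosity(make_track(square))
        assert capped and val == ft.SINUOSITY_CAP

    def test_near_closed_circle_exceeds_circling_threshold(self):
        theta = np.linspace(0, 6 * np.pi - 0.05, 400)  # 3 revolutions
        circle = np.column_stack([np.cos(theta), np.sin(theta)]) * 8
        val, _ = ft.sinuosity(make_track(circle))
        assert val > 20

    def test_reciprocal_of_displacement_ratio(self, rng):
        # sinuosity and D/(<v>T) are reciprocal path/chord ratios
        for _ in range(20):
            pos = rng.normal(size=(25, 2)).cumsum(axis=0)
            tr = make_track(pos)
            val, capped = ft.sinuosity(tr)
            _, _, ratio = ft.net_displacement(tr)
            if not capped:
                assert val * ratio == pytest.approx(1.0, rel=1e-9)


class TestStepAngles:
    def test_collinear_motion_zero(self):
        assert np.allclose(ft.step_angles(straight_track()), 0.0)

    def test_orthogonal_step(self):
        tr = make_track([(0, 0), (1, 0), (1, 1)])
        assert ft.step_angles(tr) == pytest.approx([np.pi / 2])

    def test_reversal_is_pi(self):
        tr = make_track([(0, 0), (1, 0), (0, 0)])
        assert ft.step_angles(tr) == pytest.approx([np.pi])

    def test_zero_length_steps_skipped(self):
        tr = make_track([(0, 0), (1, 0), (1, 0), (2, 0)])
        assert np.allclose(ft.step_angles(tr), 0.0)


class TestAutocorrelation:
    def test_constant_series_undefined(self):
        assert np.isnan(ft.track_autocorrelation(np.ones(50), 1.0, DT))

    def test_alternating_series_minus_one(self):
        series = np.tile([1.0, -1.0], 30)
        assert ft.track_autocorrelation(series, DT, DT) == pytest.approx(-1.0)

    def test_linear_trend_fully_correlated(self):
        series = np.arange(100, dtype=float)
        assert ft.track_autocorrelation(series, 1.0, DT) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_near_zero(self, rng):
        n = 4000
        series = rng.normal(size=n)
        val = ft.track_autocorrelation(series, 1.0, DT)
        assert abs(val) < 3 / np.sqrt(n - 15)

    def test_too_short_returns_nan_not_error(self):
        assert np.isnan(ft.track_autocorrelation(np.arange(5.0), 1.0, DT))

    def test_velocity_autocorr_straight_track_one(self):
        tr = straight_track(n=60)
        assert ft.velocity_autocorrelation(tr, 1.0) == pytest.approx(1.0)

    def test_velocity_autocorr_bounds(self, rng):
        for _ in range(10):
            pos = rng.normal(size=(80, 2)).cumsum(axis=0)
            v = ft.velocity_autocorrelation(make_track(pos), 1.0)
            assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9 or np.isnan(v)


class TestFeatureVector:
    def test_constant_velocity_closed_form(self):
        f = ft.feature_vector(straight_track(n=40, speed=23.0))
        assert f.mean_speed == pytest.approx(23.0)
        assert f.max_speed == pytest.approx(23.0)
        assert f.mean_acceleration == pytest.approx(0.0, abs=1e-8)
        assert f.displacement_ratio == pytest.approx(1.0)
        assert f.sinuosity == pytest.approx(1.0)
        assert f.mean_step_angle == pytest.approx(0.0, abs=1e-8)
        assert f.n_points == 40
        assert f.track_duration == pytest.approx(39 * DT)

    def test_deterministic_and_order_fixed(self, rng):
        pos = rng.normal(size=(50, 2)).cumsum(axis=0)
        a = ft.feature_vector(make_track(pos)).to_array()
        b = ft.feature_vector(make_track(pos)).to_array()
        np.testing.assert_array_equal(a, b)
        assert len(a) == len(ft.FEATURE_NAMES)

    def test_mean_not_exceeding_max_speed(self, rng):
        for _ in range(10):
            pos = rng.normal(size=(30, 2)).cumsum(axis=0)
            f = ft.feature_vector(make_track(pos))
            assert f.mean_speed <= f.max_speed + 1e-12

    def test_run_and_tumble_ratio_below_long_run_threshold(self):
        traj = synthetic.simulate_swimmer(
            "run_and_tumble", 20.0, 300, DT, seed=7,
            params={"mean_run_s": 0.5})
        f = ft.feature_vector(make_track(traj))
        assert f.displacement_ratio < 0.55

    def test_time_origin_shift_invariance(self, rng):
        pos = rng.normal(size=(40, 2)).cumsum(axis=0)
        tr1 = make_track(pos)
        tr2 = make_track(pos)
        tr2.t = tr2.t + 123.0
        np.testing.assert_allclose(ft.feature_vector(tr1).to_array(),
                                   ft.feature_vector(tr2).to_array())


class TestCorrelationMatrix:
    def _random_features(self, rng, n=30):
        out = []
        for _ in range(n):
            pos = rng.normal(size=(40, 2)).cumsum(axis=0) * rng.uniform(0.5, 3)
            out.append(ft.feature_vector(make_track(pos)))
        return out

    def test_matches_bruteforce_pairwise_pearson(self, rng):
        feats = self._random_features(rng)
        got = ft.feature_correlation_matrix(feats)
        X = ft.feature_matrix(feats)
        for i in range(X.shape[1]):
            for j in range(X.shape[1]):
                mask = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
                a, b = X[mask, i], X[mask, j]
                if mask.sum() < 3 or a.std() == 0 or b.std() == 0:
                    assert np.isnan(got[i, j])
                    continue
                am, bm = a - a.mean(), b - b.mean()
                r = (am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum())
                assert got[i, j] == pytest.approx(r, abs=1e-9)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        got = ft.feature_correlation_matrix(self._random_features(rng))
        finite = np.isfinite(got)
        assert np.allclose(got[finite], got.T[finite])
        diag = np.diag(got)
        assert np.allclose(diag[np.isfinite(diag)], 1.0)
        assert np.all(np.abs(got[finite]) <= 1 + 1e-9)

    def test_too_few_tracks_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.feature_correlation_matrix(self._random_features(rng, n=2))


class TestCovarianceDiffusion:
    def test_stationary_track_zero(self):
        tr = make_track(np.zeros((20, 2)))
        assert ft.covariance_diffusion(tr).D_hat == pytest.approx(0.0)

    def test_recovers_true_D(self):
        # mean over 200 simulated tracks of 150 steps at the 33 degC value
        true_D = 0.30
        est = []
        for i in range(200):
            traj = synthetic.simulate_brownian(true_D, 151, DT, seed=1000 + i)
            est.append(ft.covariance_diffusion(make_track(traj)).D_hat)
        assert np.mean(est) == pytest.approx(true_D, rel=0.05)

    def test_unbiased_under_localization_noise(self, rng):
        true_D, noise = 0.30, 0.05
        est = []
        for i in range(200):
            traj = synthetic.simulate_brownian(true_D, 151, DT, seed=5000 + i)
            traj = traj + rng.normal(0, noise, traj.shape)
            est.append(ft.covariance_diffusion(make_track(traj)).D_hat)
        assert np.mean(est) == pytest.approx(true_D, rel=0.05)

    def test_minimum_steps_enforced(self):
        tr = make_track(np.arange(8).reshape(4, 2).astype(float))
        with pytest.raises(ValueError):
            ft.covariance_diffusion(tr, min_steps=5)

    def test_recovery_across_temperatures(self):
        # Stokes-Einstein D at 22/33/44 degC recovered within 5%
        for celsius in (22.0, 33.0, 44.0):
            true_D = brownian_D_um2_s(celsius + 273.15, 1.0)
            est = []
            for i in range(200):
                traj = synthetic.simulate_brownian(
                    true_D, 151, DT, seed=int(celsius) * 100 + i)
                est.append(ft.covariance_diffusion(make_track(traj)).D_hat)
            assert np.mean(est) == pytest.approx(true_D, rel=0.05)


class TestSampleDiffusion:
    def test_population_mean_and_flag(self):
        tracks = [make_track(synthetic.simulate_brownian(0.5, 151, DT, seed=i))
                  for i in range(200)]
        summary = ft.sample_diffusion(tracks)
        assert summary.mean_D == pytest.approx(0.5, rel=0.05)
        assert summary.sd_D > 0
        assert not summary.flagged

    def test_single_track_flagged(self):
        tracks = [make_track(synthetic.simulate_brownian(0.5, 151, DT, seed=0))]
        assert ft.sample_diffusion(tracks, min_tracks=10).flagged

    def test_mixture_mean_between_components(self):
        tracks = [make_track(synthetic.simulate_brownian(d, 151, DT, seed=i))
                  for i, d in enumerate([0.2] * 50 + [1.0] * 50)]
        summary = ft.sample_diffusion(tracks)
        assert 0.2 < summary.mean_D < 1.0
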