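"""Time-of-flight speed estimation: projection, arrival extraction,
regression/RANSAC/Radon, and the bias/scaling laws they must obey."""
import numpy as np
import pytest

import sweiproc as sw
from sweiproc.datatypes import ArrivalTimeProfile
from sweiproc.errors import ParameterError, StateError
from sweiproc.sws import RadonConfig, RoiSpec, radon_sum_surface

from conftest import motion_2d


def spacetime(scen, v=None, x=None, pri=1e-4, n_track=80):
    scen = scen if v is None else sw.ShearWaveScenario(
        true_sws=v, pulse_sigma=scen.pulse_sigma, amplitude=scen.amplitude,
        origin_x=0.0, decay_exponent=scen.decay_exponent,
        start_time=scen.start_time, seed=scen.seed)
    if x is None:
        x = np.arange(1e-3, 4.01e-3, 0.5e-3)
    times, labels = sw.frame_schedule(pri, 4, 3, n_track)
    return scen, sw.simulate_shear_wave_motion(scen, x, times, labels)


class TestProjection:
    def test_single_axial_sample_identity(self, phantom_motion):
        data3 = phantom_motion.data[None, :, :]
        mf = sw.MotionField(data=data3, quantity="displacement",
                            times=phantom_motion.times,
                            lateral_positions=phantom_motion.lateral_positions,
                            axial_positions=np.array([20e-3]))
        roi = RoiSpec(focal_depth=20e-3, dof_span=5e-3, lateral_min=0.0,
                      lateral_max=1.0)
        out = sw.project_to_spacetime(mf, roi)
        assert np.array_equal(out.data, phantom_motion.data)

    def test_axially_uniform_field_equals_any_row(self, phantom_motion):
        data3 = np.repeat(phantom_motion.data[None, :, :], 8, axis=0)
        mf = sw.MotionField(data=data3, quantity="displacement",
                            times=phantom_motion.times,
                            lateral_positions=phantom_motion.lateral_positions,
                            axial_positions=18e-3 + 1e-3 * np.arange(8))
        roi = RoiSpec(focal_depth=21e-3, dof_span=6e-3, lateral_min=0.0,
                      lateral_max=1.0)
        out = sw.project_to_spacetime(mf, roi)
        assert np.allclose(out.data, phantom_motion.data, rtol=1e-12)

    def test_beamwidth_exclusion_drops_near_positions(self):
        """lateral_min = Fλ (F = 1.5, λ = 0.7 mm) drops the first 3 of
        positions spaced 0.35 mm from the origin."""
        f_num, lam = 1.5, 0.7e-3
        x = 0.35e-3 * np.arange(1, 13)  # 0.35 … 4.2 mm
        data = np.zeros((len(x), 20))
        mf = motion_2d(data, 1e-4, x=x)
        roi = RoiSpec(focal_depth=0.0, dof_span=1.0,
                      lateral_min=f_num * lam, lateral_max=1.0)
        out = sw.project_to_spacetime(mf, roi)
        assert len(out.lateral_positions) == len(x) - 3
        assert out.lateral_positions[0] == pytest.approx(0.35e-3 * 4)

    def test_empty_selection_rejected(self, phantom_motion):
        roi = RoiSpec(focal_depth=0.0, dof_span=1.0, lateral_min=0.9,
                      lateral_max=1.0)
        with pytest.raises(ParameterError, match="lateral"):
            sw.project_to_spacetime(phantom_motion, roi)


class TestArrivalExtraction:
    def test_analytic_arrival_times(self, phantom_scenario):
        scen, st = spacetime(phantom_scenario, v=1.0)
        prof = sw.extract_arrival_times(st, "peak_displacement", 10)
        expected = scen.arrival_time(prof.lateral_positions)
        assert np.max(np.abs(prof.arrival_times - expected)) \
            < 1e-4 / (2 * 10) + 1e-6

    def test_xcorr_lags_on_shifted_traces(self):
        dt = 1e-4
        t = np.arange(64) * dt
        base = np.exp(-(t - 2e-3) ** 2 / (2 * (0.5e-3) ** 2))
        shift = 3  # frames
        data = np.stack([base, np.roll(base, shift), np.roll(base, 2 * shift)])
        st = motion_2d(data, dt, x=np.array([1e-3, 2e-3, 3e-3]))
        prof = sw.extract_arrival_times(st, "xcorr", 1)
        lags = np.diff(prof.arrival_times)
        assert np.allclose(lags, shift * dt, atol=1e-12)

    def test_peak_velocity_leads_displacement_by_sigma(self, phantom_scenario):
        scen, st = spacetime(phantom_scenario)
        pd = sw.extract_arrival_times(st, "peak_displacement", 10)
        pv = sw.extract_arrival_times(st, "peak_velocity", 10)
        # Gaussian pulse: the velocity extremum precedes the peak by σ
        offset = pd.arrival_times - pv.arrival_times
        assert np.allclose(offset, scen.pulse_sigma, atol=2e-5)

    def test_no_wave_positions_dropped(self):
        dt = 1e-4
        data = np.zeros((3, 40))
        data[0, 10] = 1.0  # only the first trace carries a wave
        st = motion_2d(data, dt, x=np.array([1e-3, 2e-3, 3e-3]))
        with pytest.raises(StateError):
            with pytest.warns(UserWarning, match="dropped"):
                sw.extract_arrival_times(st, "peak_displacement", 2)


class TestRegression:
    def test_exact_profile_recovers_speed(self):
        x = np.arange(1e-3, 4.01e-3, 0.5e-3)
        prof = ArrivalTimeProfile(lateral_positions=x, arrival_times=x / 1.1,
                                  feature="peak_displacement")
        est = sw.fit_sws_regression(prof)
        assert est.sws == pytest.approx(1.1, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_intercept_invariance(self):
        x = np.arange(1e-3, 4.01e-3, 0.5e-3)
        for offset in (0.0, 1.7e-3):
            prof = ArrivalTimeProfile(lateral_positions=x,
                                      arrival_times=x / 2.0 + offset,
                                      feature="peak_displacement")
            assert sw.fit_sws_regression(prof).sws == pytest.approx(2.0,
                                                                    rel=1e-12)

    def test_negative_slope_flagged_not_raised(self):
        x = np.arange(1e-3, 4.01e-3, 0.5e-3)
        prof = ArrivalTimeProfile(lateral_positions=x, arrival_times=-x / 1.1,
                                  feature="peak_displacement")
        est = sw.fit_sws_regression(prof)
        assert not est.success and np.isnan(est.sws)

    def test_outlier_shifts_ols_but_not_ransac(self):
        x = 0.5e-3 * np.arange(1, 9)
        t = x / 2.0
        t_out = t.copy()
        t_out[3] += 1.5e-3  # gross outlier
        prof = ArrivalTimeProfile(lateral_positions=x, arrival_times=t_out,
                                  feature="peak_displacement")
        ols = sw.fit_sws_regression(prof)
        ransac = sw.fit_sws_ransac(prof, threshold=1e-4, iterations=500,
                                   seed=3)
        assert abs(ols.sws - 2.0) / 2.0 > 0.05
        assert abs(ransac.sws - 2.0) / 2.0 < 0.01


class TestRansac:
    def make_profile(self, v=2.0, n=20, outlier_fraction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = 0.25e-3 * np.arange(1, n + 1)
        t = x / v
        n_out = int(round(outlier_fraction * n))
        idx = rng.choice(n, size=n_out, replace=False)
        t[idx] += rng.uniform(0.5e-3, 2e-3, size=n_out) \
            * rng.choice([-1, 1], size=n_out)
        return ArrivalTimeProfile(lateral_positions=x, arrival_times=t,
                                  feature="peak_displacement")

    def test_outlier_free_matches_ols(self):
        prof = self.make_profile()
        ols = sw.fit_sws_regression(prof)
        rs = sw.fit_sws_ransac(prof, threshold=1e-4, iterations=200, seed=0)
        assert rs.sws == pytest.approx(ols.sws, rel=1e-12)
        assert rs.inlier_fraction == 1.0

    def test_thirty_percent_outliers(self):
        prof = self.make_profile(outlier_fraction=0.3, seed=5)
        rs = sw.fit_sws_ransac(prof, threshold=1e-4, iterations=2000, seed=1)
        assert rs.sws == pytest.approx(2.0, rel=0.02)
        assert rs.inlier_fraction == pytest.approx(0.7, abs=0.15)

    def test_success_probability_bound(self):
        """With 30 % outliers, ≥ 99 % of seeds succeed at 2000 iterations
        (combinatorial bound 1 − (1 − w²)^k is ≈ 1)."""
        prof = self.make_profile(outlier_fraction=0.3, seed=5)
        ok = sum(
            abs(sw.fit_sws_ransac(prof, 1e-4, iterations=2000, seed=s).sws
                - 2.0) / 2.0 < 0.02
            for s in range(50))
        assert ok >= 50 * 0.99 - 1e-9

    def test_deterministic_for_fixed_seed(self):
        prof = self.make_profile(outlier_fraction=0.2, seed=2)
        a = sw.fit_sws_ransac(prof, 1e-4, iterations=500, seed=9)
        b = sw.fit_sws_ransac(prof, 1e-4, iterations=500, seed=9)
        assert a.sws == b.sws and a.inlier_fraction == b.inlier_fraction

    def test_no_consensus_fails_gracefully(self):
        rng = np.random.default_rng(0)
        x = 0.5e-3 * np.arange(1, 7)
        t = rng.uniform(0, 5e-3, 6)
        prof = ArrivalTimeProfile(lateral_positions=x, arrival_times=np.sort(t) * 0
                                  + t, feature="peak_displacement")
        est = sw.fit_sws_ransac(prof, threshold=1e-9, iterations=50, seed=0)
        assert not est.success


class TestRadon:
    def test_recovers_phantom_speed(self, phantom_scenario):
        scen, st = spacetime(phantom_scenario)  # 1.1 m/s
        cfg = RadonConfig(x_start=1e-3, x_end=4e-3, time_upsample=10,
                          speed_range=(0.25, 10.0))
        est = sw.fit_sws_radon(st, cfg)
        assert est.success
        assert est.sws == pytest.approx(1.1, rel=0.01)

    def test_matches_bruteforce_enumeration(self):
        """Vectorised Radon search equals explicit trajectory enumeration
        on small noisy grids (10 seeded draws)."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            dt = 2e-4
            x = 0.25e-3 * np.arange(1, 17)       # 16 positions
            t = dt * np.arange(50)
            v_true = rng.uniform(0.8, 3.0)
            tau = t[None, :] - 1e-3 - x[:, None] / v_true
            data = np.exp(-tau**2 / (2 * (0.8e-3) ** 2)) \
                + 0.2 * rng.standard_normal((16, 50))
            st = motion_2d(data, dt, x=x)
            cfg = RadonConfig(x_start=float(x[0]), x_end=float(x[-1]),
                              time_upsample=2, speed_range=(0.3, 6.0))
            est = sw.fit_sws_radon(st, cfg)

            # independent oracle: explicit loops over the same lattice
            from scipy.interpolate import CubicSpline
            n_fine = (len(t) - 1) * 2 + 1
            t_fine = np.linspace(t[0], t[-1], n_fine)
            traces = CubicSpline(t, np.abs(data), axis=-1)(t_fine)
            best = (-np.inf, None)
            span = x[-1] - x[0]
            for i_s in range(n_fine):
                for i_e in range(n_fine):
                    transit = t_fine[i_e] - t_fine[i_s]
                    if transit <= 0:
                        continue
                    v = span / transit
                    if not (0.3 <= v <= 6.0):
                        continue
                    s = 0.0
                    for j in range(len(x)):
                        tj = t_fine[i_s] + (x[j] - x[0]) / span * transit
                        s += np.interp(tj, t_fine, traces[j])
                    if s > best[0] or (s == best[0] and v < best[1]):
                        best = (s, v)
            assert est.sws == pytest.approx(best[1], rel=1e-12)

    def test_uniform_field_fails_flat_surface(self):
        st = motion_2d(np.ones((10, 40)), 1e-4,
                       x=0.5e-3 * np.arange(1, 11))
        cfg = RadonConfig(x_start=0.5e-3, x_end=5e-3)
        est = sw.fit_sws_radon(st, cfg)
        assert not est.success and np.isnan(est.sws)

    def test_tie_breaks_to_slowest_speed(self):
        t_fine, _, sums, speeds = radon_sum_surface(
            motion_2d(np.ones((10, 40)) * 0.0, 1e-4,
                      x=0.5e-3 * np.arange(1, 11)),
            RadonConfig(x_start=0.5e-3, x_end=5e-3))
        # all-zero field: every trajectory sums to 0; fit must choose slowest
        est = sw.fit_sws_radon(
            motion_2d(np.zeros((10, 40)), 1e-4, x=0.5e-3 * np.arange(1, 11)),
            RadonConfig(x_start=0.5e-3, x_end=5e-3))
        assert (not est.success) or est.sws == pytest.approx(
            np.nanmin(speeds), rel=1e-9)


class TestEstimatorLaws:
    @pytest.mark.parametrize("v", [0.5, 1.1, 2.0, 4.0])
    def test_method_agreement_across_speeds(self, phantom_scenario, v):
        """All three estimators within 2 % of truth on noiseless data."""
        pri = 1e-4
        n_track = int(4.5e-3 / v / pri) + 60
        scen, st = spacetime(phantom_scenario, v=v, n_track=n_track)
        ests = [
            sw.fit_sws_regression(
                sw.extract_arrival_times(st, "peak_displacement", 10)),
            sw.fit_sws_ransac(
                sw.extract_arrival_times(st, "peak_displacement", 10),
                threshold=pri, iterations=500, seed=0),
            sw.fit_sws_radon(st, RadonConfig(x_start=1e-3, x_end=4e-3,
                                             time_upsample=10,
                                             speed_range=(0.25, 10.0))),
        ]
        for est in ests:
            assert est.success
            assert est.sws == pytest.approx(v, rel=0.02)

    @pytest.mark.parametrize("eps", [0.05, -0.05])
    def test_pri_error_propagates_inversely_to_sws(self, phantom_scenario,
                                                   eps):
        """Scaling the time axis by (1+ε) scales every estimate by 1/(1+ε)."""
        scen, st = spacetime(phantom_scenario, v=2.0, n_track=80)
        scaled = st.copy_with(times=st.times * (1 + eps))
        base = {
            "regression": sw.fit_sws_regression(
                sw.extract_arrival_times(st, "peak_displacement", 10)).sws,
            "ransac": sw.fit_sws_ransac(
                sw.extract_arrival_times(st, "peak_displacement", 10),
                threshold=1e-4, iterations=300, seed=1).sws,
            "radon": sw.fit_sws_radon(
                st, RadonConfig(1e-3, 4e-3, 10, (0.25, 10.0))).sws,
        }
        scaled_est = {
            "regression": sw.fit_sws_regression(
                sw.extract_arrival_times(scaled, "peak_displacement",
                                         10)).sws,
            "ransac": sw.fit_sws_ransac(
                sw.extract_arrival_times(scaled, "peak_displacement", 10),
                threshold=1e-4 * (1 + eps), iterations=300, seed=1).sws,
            "radon": sw.fit_sws_radon(
                scaled, RadonConfig(1e-3, 4e-3, 10, (0.25, 10.0))).sws,
        }
        for method in base:
            assert scaled_est[method] == pytest.approx(
                base[method] / (1 + eps), rel=1e-3), method

    def test_near_field_inclusion_biases_sws_downward(self):
        """Early (diffraction-contaminated) arrivals inside the excitation
        beamwidth pull the regression speed down."""
        v = 1.5
        beamwidth = 1.05e-3
        x = 0.35e-3 * np.arange(1, 13)
        t = x / v
        inside = x <= beamwidth
        t[inside] = 0.25 * x[inside] / v  # near-field arrivals come early
        prof_all = ArrivalTimeProfile(lateral_positions=x, arrival_times=t,
                                      feature="peak_displacement")
        prof_out = ArrivalTimeProfile(lateral_positions=x[~inside],
                                      arrival_times=t[~inside],
                                      feature="peak_displacement")
        est_all = sw.fit_sws_regression(prof_all)
        est_out = sw.fit_sws_regression(prof_out)
        assert est_all.sws < est_out.sws

    def test_displacement_and_velocity_features_agree(self, phantom_scenario):
        scen, st = spacetime(phantom_scenario)
        vd = sw.fit_sws_regression(
            sw.extract_arrival_times(st, "peak_displacement", 10)).sws
        vv = sw.fit_sws_regression(
            sw.extract_arrival_times(st, "peak_velocity", 10)).sws
        assert vd == pytest.approx(1.1, rel=0.02)
        assert vv == pytest.approx(1.1, rel=0.02)
        assert vd == pytest.approx(vv, rel=0.02)
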