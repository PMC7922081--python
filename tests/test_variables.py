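"""Filtering and the per-frame plantar-pressure variables, against loop oracles."""

import numpy as np
import pytest

from insolesim import synthetic, variables
from insolesim.core import ZeroingProfile


class TestButterworth:
    def test_dc_gain_is_one(self):
        out = variables.butterworth_lowpass(np.full(200, 4.2), fs=100.0)
        np.testing.assert_allclose(out, 4.2, atol=1e-9)

    def test_attenuation_at_cutoff_matches_squared_magnitude(self):
        """Forward-backward filtering squares |H|; a 3rd-order Butterworth
        has |H(fc)|^2 = 1/2 at its cutoff fc = fs/8."""
        fs = 100.0
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * (fs / 8) * t)
        y = variables.butterworth_lowpass(x, fs)
        amp = np.max(np.abs(y[1000:3000]))  # steady-state, away from edges
        assert amp == pytest.approx(0.5, rel=1e-3)

    def test_analytic_attenuation_off_cutoff(self):
        # digital order-3 Butterworth: |H(w)|^2 = 1/(1 + (tan(w/2)/tan(wc/2))^6)
        fs = 100.0
        f = fs / 4  # twice the cutoff
        t = np.arange(6000) / fs
        y = variables.butterworth_lowpass(np.sin(2 * np.pi * f * t), fs)
        amp = np.max(np.abs(y[2000:4000]))
        w, wc = np.pi / 2, np.pi / 4
        expected = 1.0 / (1.0 + (np.tan(w / 2) / np.tan(wc / 2)) ** 6)
        assert amp == pytest.approx(expected, rel=5e-3)

    def test_white_noise_variance_reduced(self, rng):
        x = rng.normal(0, 1, 2000)
        y = variables.butterworth_lowpass(x, 100.0)
        assert y.var() < x.var()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="padding"):
            variables.butterworth_lowpass(np.ones(5), 100.0)


class TestPerFrameVariables:
    def test_peak_single_sensor(self, recording_factory):
        p = np.zeros((1, 99))
        p[0, 7] = 5.0
        assert variables.peak_pressure(recording_factory(p))[0] == 5.0

    def test_peak_zero_frame(self, recording_factory):
        assert variables.peak_pressure(recording_factory(np.zeros((1, 99))))[0] == 0.0

    def test_mean_pressure_contact_mean(self, recording_factory):
        p = np.zeros((1, 99))
        p[0, 3] = 4.0
        rec = recording_factory(p)
        assert variables.mean_pressure(rec, contact_threshold=0.0)[0] == 4.0

    def test_mean_pressure_uniform_field(self, recording_factory):
        rec = recording_factory(np.full((2, 99), 0.7))
        np.testing.assert_allclose(
            variables.mean_pressure(rec, contact_threshold=0.0), 0.7
        )

    def test_grf_uniform_arithmetic(self, recording_factory):
        sensors = synthetic.generate_template("38-39", "nominal5mm")
        rec = recording_factory(np.full((1, 99), 0.01), sensors=sensors)
        assert variables.grf(rec)[0] == pytest.approx(99 * 0.01 * 25.0)  # 24.75 %BW

    def test_grf_zero_frame(self, recording_factory):
        assert variables.grf(recording_factory(np.zeros((1, 99))))[0] == 0.0

    def test_random_frames_match_loop_oracles(self, recording_factory, rng):
        rec = recording_factory(rng.uniform(0, 1, (15, 99)))
        thr = 0.3
        pk = variables.peak_pressure(rec)
        mp = variables.mean_pressure(rec, contact_threshold=thr)
        g = variables.grf(rec)
        ca = variables.contact_area(rec, contact_threshold=thr)
        for t in range(rec.n_frames):
            vals = rec.pressures[t]
            assert pk[t] == pytest.approx(max(vals), rel=1e-12)
            contact = [v for v in vals if v > thr]
            assert mp[t] == pytest.approx(
                sum(contact) / len(contact) if contact else 0.0, rel=1e-12
            )
            assert g[t] == pytest.approx(
                sum(v * s.area_mm2 for v, s in zip(vals, rec.sensors)), rel=1e-12
            )
            area = sum(s.area_mm2 for v, s in zip(vals, rec.sensors) if v > thr)
            assert ca[t] == pytest.approx(
                100 * area / rec.total_surface_mm2, rel=1e-12
            )


class TestCop:
    def test_two_equal_sensors_midpoint(self, recording_factory, toy_grid):
        p = np.zeros((1, 16))
        p[0, 0] = p[0, 3] = 1.0  # centers x=25 and x=55 in the toy grid
        rec = recording_factory(p, sensors=toy_grid)
        x, y = variables.cop_eq1(rec)
        assert x[0] == pytest.approx(40.0)

    def test_single_active_sensor_at_its_center(self, recording_factory, template_38):
        p = np.zeros((2, 99))
        p[:, 42] = 2.0
        rec = recording_factory(p)
        x, y = variables.cop_eq1(rec)
        assert x[0] == pytest.approx(template_38[42].center_x)
        assert y[0] == pytest.approx(template_38[42].center_y)
        x2, y2 = variables.cop_eq2(rec)
        assert x2[0] == pytest.approx(template_38[42].center_x)

    def test_unloaded_frames_flagged_missing(self, recording_factory):
        p = np.zeros((3, 99))
        p[1, 0] = 1.0
        x, y = variables.cop_eq1(recording_factory(p))
        assert np.isnan(x[0]) and np.isnan(x[2]) and np.isfinite(x[1])

    def test_eq1_matches_loop_oracle(self, recording_factory, rng):
        rec = recording_factory(rng.uniform(0, 1, (10, 99)))
        x, y = variables.cop_eq1(rec)
        for t in range(10):
            num_x = sum(s.center_x * v for s, v in zip(rec.sensors, rec.pressures[t]))
            num_y = sum(s.center_y * v for s, v in zip(rec.sensors, rec.pressures[t]))
            den = sum(rec.pressures[t])
            assert x[t] == pytest.approx(num_x / den, rel=1e-12)
            assert y[t] == pytest.approx(num_y / den, rel=1e-12)

    def test_eq2_matches_two_pass_oracle(self, recording_factory, rng):
        rec = recording_factory(rng.uniform(0, 1, (12, 99)))
        x, y = variables.cop_eq2(rec)
        peaks = [max(rec.pressures[:, i]) for i in range(99)]  # pass 1
        for t in range(12):
            w = [rec.pressures[t, i] / peaks[i] for i in range(99)]
            den = sum(w)
            assert x[t] == pytest.approx(
                sum(wi * s.center_x for wi, s in zip(w, rec.sensors)) / den, rel=1e-12
            )
            assert y[t] == pytest.approx(
                sum(wi * s.center_y for wi, s in zip(w, rec.sensors)) / den, rel=1e-12
            )

    def test_eq2_identical_profiles_stay_at_midpoint(self, recording_factory, toy_grid):
        p = np.zeros((6, 16))
        profile = np.array([0.1, 0.5, 1.0, 0.7, 0.3, 0.05])
        p[:, 0] = profile
        p[:, 3] = profile  # x = 25 and 55
        x, _ = variables.cop_eq2(recording_factory(p, sensors=toy_grid))
        np.testing.assert_allclose(x, 40.0, rtol=1e-12)

    def test_cop_bounded_by_sensor_centers(self, recording_factory, rng):
        rec = recording_factory(rng.uniform(0, 1, (10, 99)))
        x, y = variables.cop_eq1(rec)
        centers = rec.sensor_centers
        assert np.all(x >= centers[:, 0].min()) and np.all(x <= centers[:, 0].max())
        assert np.all(y >= centers[:, 1].min()) and np.all(y <= centers[:, 1].max())


class TestDcopContact:
    def test_dcop_examples(self, recording_factory):
        rec = recording_factory(np.zeros((1, 99)))
        rec.total_surface_mm2 = 10000.0
        d = variables.dcop(np.array([3.0]), np.array([4.0]), rec)
        assert d[0] == pytest.approx(0.05)
        d0 = variables.dcop(np.array([0.0]), np.array([0.0]), rec)
        assert d0[0] == 0.0

    def test_all_16_simulated_sensors_active_contact_area(
        self, recording_factory, default_layout_38
    ):
        rec = recording_factory(
            np.full((1, 16), 1.0), sensors=default_layout_38.sensors
        )
        ca = variables.contact_area(rec, contact_threshold=0.0)
        assert ca[0] == pytest.approx(100 * 3600.0 / 15787.0, rel=1e-9)  # ~22.8

    def test_contact_area_zero_frame(self, recording_factory):
        ca = variables.contact_area(recording_factory(np.zeros((1, 99))))
        assert ca[0] == 0.0


class TestComputeAll:
    def test_constant_recording_all_series_constant(self, recording_factory):
        rec = recording_factory(np.full((100, 99), 0.04))
        vs = variables.compute_all(rec, contact_threshold=0.0)
        for name in ("peak_pressure", "mean_pressure", "grf", "contact_area", "dcop"):
            series = getattr(vs, name)
            np.testing.assert_allclose(series, series[0], rtol=1e-9)
        np.testing.assert_allclose(vs.cop1_x, vs.cop1_x[0], rtol=1e-12)

    def test_filter_toggle_identical_on_constant_input(self, recording_factory):
        rec = recording_factory(np.full((100, 99), 0.04))
        a = variables.compute_all(rec, contact_threshold=0.0, filtered=True)
        b = variables.compute_all(rec, contact_threshold=0.0, filtered=False)
        np.testing.assert_allclose(a.grf, b.grf, atol=1e-9)

    def test_grf_mean_consistency_with_shared_area(self, recording_factory, rng):
        """With equal-area sensors, grf = contact mean x n_contact x area."""
        sensors = synthetic.generate_template("38-39", "nominal5mm")
        rec = recording_factory(rng.uniform(0.01, 1, (8, 99)), sensors=sensors)
        vs_mean = variables.mean_pressure(rec, contact_threshold=0.0)
        n_contact = (rec.pressures > 0).sum(axis=1)
        np.testing.assert_allclose(
            variables.grf(rec), vs_mean * n_contact * 25.0, rtol=1e-12
        )

    def test_surface_mean_policy_proportional_to_grf(self, gait_trial):
        rec, _, _ = gait_trial
        vs = variables.compute_all(rec, mean_policy="surface", filtered=False)
        np.testing.assert_allclose(
            vs.mean_pressure, vs.grf / rec.total_surface_mm2, rtol=1e-12
        )

    def test_computed_cop_tracks_analytic_cop(self, gait_trial):
        rec, _, gt = gait_trial
        vs = variables.compute_all(rec, filtered=False)
        m = np.isfinite(gt.cop[:, 0])
        err = np.hypot(vs.cop1_x[m] - gt.cop[m, 0], vs.cop1_y[m] - gt.cop[m, 1])
        assert np.nanmax(err) <= 5.0  # within one nominal sensor pitch

    def test_zeroing_profile_threshold_accepted(self, gait_trial):
        rec, _, _ = gait_trial
        zp = ZeroingProfile(np.full(99, 5e-4))
        vs = variables.compute_all(rec, contact_threshold=zp, filtered=False)
        assert np.all(vs.contact_area >= 0) and np.all(vs.contact_area <= 100)
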