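import io
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from ovclamp.control import IControllerConfig
from ovclamp.plant import LightInput, make_preset, static_voltage
from ovclamp.sensor import sensor_preset
from ovclamp.session import (
    ProtocolSpec,
    Waveform,
    read_results,
    run_current_clamp,
    run_on_the_run,
    run_pseudo_iv,
    run_session,
    write_results,
)

CAL = 300  # short calibration keeps the suite fast; decay still well sampled


def short_proto(**kw):
    defaults = dict(targets=[0.0, -5.0, 5.0, 0.0], frames_per_step=120,
                    calibration_frames=CAL, seed=11)
    defaults.update(kw)
    return ProtocolSpec(**defaults)


class TestRunSession:
    def test_four_step_reaches_and_holds_every_plateau(
        self, bwm_plant, bwm_sensor, bwm_controller
    ):
        # a short calibration biases the bleach extrapolation (slow membrane
        # noise leaks into the fit), so use a realistic 8 s here
        res = run_session(short_proto(calibration_frames=800),
                          bwm_plant, bwm_sensor, bwm_controller)
        for (i0, i1), target in zip(res.step_bounds(), res.step_targets()):
            tail = res.dff_pct[i1 - 40 : i1]
            assert abs(tail.mean() - target) <= 1.5 * bwm_controller.tolerance

    def test_zero_gain_keeps_wavelength_constant(
        self, bwm_plant, bwm_sensor, bwm_controller
    ):
        ctrl = IControllerConfig(ki=0.0, tolerance=1.0,
                                 start_wavelength=bwm_controller.start_wavelength)
        res = run_session(short_proto(), bwm_plant, bwm_sensor, ctrl)
        assert np.all(res.wavelength_nm == ctrl.start_wavelength)

    def test_noiseless_plateau_matches_static_map_inversion(
        self, bwm_plant_quiet, bwm_sensor, fine_controller
    ):
        """Closed-loop fixed point equals bisection on the plant's static map."""
        res = run_session(
            short_proto(targets=[4.0], frames_per_step=150),
            bwm_plant_quiet, bwm_sensor, fine_controller,
        )
        lam_loop = res.wavelength_nm[-30:].mean()
        target_v = bwm_plant_quiet.resting_potential + 4.0 / bwm_sensor.dff_per_mv
        lam_oracle = brentq(
            lambda l: static_voltage(LightInput(l, 1.0, laser_on=True),
                                     bwm_plant_quiet) - target_v,
            400.0, 600.0,
        )
        # per-step resolution of the dead-band controller: ki * tolerance
        assert abs(lam_loop - lam_oracle) <= fine_controller.ki * fine_controller.tolerance + 1.0

    def test_same_seed_byte_identical_results_file(
        self, bwm_plant, bwm_sensor, bwm_controller
    ):
        bufs = []
        for _ in range(2):
            res = run_session(short_proto(), bwm_plant, bwm_sensor, bwm_controller)
            buf = io.StringIO()
            write_results(res, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_statuses_cover_all_frames(self, bwm_plant, bwm_sensor, bwm_controller):
        res = run_session(short_proto(), bwm_plant, bwm_sensor, bwm_controller)
        assert set(res.status[: res.calibration_frames]) == {"C"}
        clamp = res.status[res.clamp_slice()]
        assert set(clamp) <= {"H", "A", "L"}
        # holding frames leave the wavelength unchanged on the next frame
        lam = res.wavelength_nm
        for k in range(res.calibration_frames, len(lam) - 1):
            if res.status[k] == "H":
                assert lam[k + 1] == lam[k]

    def test_record_count(self, bwm_plant, bwm_sensor, bwm_controller):
        proto = short_proto()
        res = run_session(proto, bwm_plant, bwm_sensor, bwm_controller)
        assert len(res.frame) == proto.calibration_frames + 4 * 120


class TestPseudoIV:
    def test_eleven_steps_hit_targets_and_wavelength_monotone(
        self, bwm_plant_quiet, bwm_sensor, fine_controller
    ):
        iv = run_pseudo_iv((-5.0, 5.0), bwm_plant_quiet, bwm_sensor, fine_controller,
                           frames_per_step=100, calibration_frames=CAL, seed=0)
        assert len(iv.target_dff) == 11
        assert np.allclose(np.diff(iv.target_dff), 1.0)
        assert np.all(np.abs(iv.achieved_dff - iv.target_dff) <= 2 * fine_controller.tolerance)
        # red wavelengths depolarize: wavelength increases with the target
        assert np.all(np.diff(iv.wavelength) > 0)

    def test_window_uses_final_quarter(self, bwm_plant, bwm_sensor, fine_controller):
        iv = run_pseudo_iv((-2.0, 2.0), bwm_plant, bwm_sensor, fine_controller,
                           frames_per_step=8, calibration_frames=CAL, seed=0)
        # 8-frame steps -> 2-frame windows; all values must be finite
        assert np.all(np.isfinite(iv.achieved_dff))
        assert np.all(np.isfinite(iv.wavelength))

    def test_forward_inverse_round_trip(
        self, bwm_plant_quiet, bwm_sensor, fine_controller
    ):
        """Replaying the clamp wavelengths open loop reproduces the dF/F0 pairs."""
        iv = run_pseudo_iv((-5.0, 5.0), bwm_plant_quiet, bwm_sensor, fine_controller,
                           frames_per_step=100, calibration_frames=CAL, seed=0)
        wf = Waveform("steps", steps=[(w, 100) for w in iv.wavelength])
        res = run_current_clamp(
            wf, bwm_plant_quiet, bwm_sensor,
            start_wavelength=fine_controller.start_wavelength,
            calibration_frames=CAL, seed=0,
        )
        i0 = res.calibration_frames
        for k, expected in enumerate(iv.achieved_dff):
            window = res.dff_pct[i0 + k * 100 + 75 : i0 + (k + 1) * 100]
            assert window.mean() == pytest.approx(expected, abs=3 * fine_controller.tolerance)

    def test_invalid_limits(self, bwm_plant, bwm_sensor, fine_controller):
        with pytest.raises(ValueError):
            run_pseudo_iv((5.0, -5.0), bwm_plant, bwm_sensor, fine_controller)


class TestCurrentClamp:
    def test_zero_intensity_waveform_is_flat_noise(self, bwm_plant, bwm_sensor):
        wf = Waveform("pulse", wavelength=590.0, duration_ms=0.0, pre_ms=0.0,
                      total_frames=150)
        wf.intensity = 0.0
        res = run_current_clamp(wf, bwm_plant, bwm_sensor, start_wavelength=519.6,
                                calibration_frames=CAL, seed=5)
        # monochromator dark: only the laser crosstalk depolarizes slightly,
        # so dF/F0 drifts up; it must stay bounded and noisy, with no steps
        d = res.dff_pct[res.clamp_slice()]
        assert np.all(np.isfinite(d))
        assert d.std() < 10.0

    def test_ramp_gives_monotone_depolarization(self, bwm_plant_quiet, bwm_sensor):
        wf = Waveform("ramp", lambda_start=400.0, lambda_end=600.0, total_frames=200)
        res = run_current_clamp(wf, bwm_plant_quiet, bwm_sensor,
                                start_wavelength=519.6, calibration_frames=CAL, seed=0)
        d = res.dff_pct[res.clamp_slice()]
        assert d[-20:].mean() > d[:20].mean() + 5.0
        smooth = np.convolve(d, np.ones(20) / 20, mode="valid")
        assert np.all(np.diff(smooth[::10]) > -0.5)

    def test_pharynx_pulse_elicits_ap(self):
        plant = make_preset("pharynx")
        sensor = sensor_preset("pharynx")
        wf = Waveform("pulse", wavelength=590.0, duration_ms=400.0, pre_ms=500.0,
                      total_frames=200)
        res = run_current_clamp(wf, plant, sensor, start_wavelength=511.1,
                                calibration_frames=400, seed=2)
        v = res.voltage_mv[res.clamp_slice()]
        assert v.max() > plant.resting_potential + 20.0

    def test_out_of_limits_rejected(self, bwm_plant, bwm_sensor):
        wf = Waveform("ramp", lambda_start=300.0, lambda_end=600.0, total_frames=50)
        with pytest.raises(ValueError):
            run_current_clamp(wf, bwm_plant, bwm_sensor, calibration_frames=CAL)


class TestOnTheRun:
    def test_single_entry_equals_step_protocol(
        self, bwm_plant, bwm_sensor, bwm_controller
    ):
        res_a = run_on_the_run([(0.0, 3.0)], 150, bwm_plant, bwm_sensor,
                               bwm_controller, calibration_frames=CAL, seed=4)
        res_b = run_session(short_proto(targets=[3.0], frames_per_step=150, seed=4),
                            bwm_plant, bwm_sensor, bwm_controller)
        np.testing.assert_array_equal(res_a.dff_pct, res_b.dff_pct)
        np.testing.assert_array_equal(res_a.wavelength_nm, res_b.wavelength_nm)

    def test_alternating_targets_reenter_tolerance(
        self, bwm_plant, bwm_sensor, bwm_controller
    ):
        sched = [(0.0, 3.0), (1000.0, -3.0), (2000.0, 3.0), (3000.0, -3.0)]
        res = run_on_the_run(sched, 400, bwm_plant, bwm_sensor, bwm_controller,
                             calibration_frames=CAL, seed=6)
        i0 = res.calibration_frames
        for t_ms, target in sched:
            seg = res.dff_pct[i0 + int(t_ms / 10) : i0 + int(t_ms / 10) + 100]
            dev = np.abs(seg - target)
            assert np.any(dev <= bwm_controller.tolerance)

    def test_limit_recovery_status_sequence(self, bwm_plant, bwm_sensor):
        """An unreachable target saturates; a feasible one recovers to holding."""
        ctrl = IControllerConfig(ki=7.0, tolerance=1.0, start_wavelength=519.6)
        res = run_on_the_run([(0.0, 40.0), (1500.0, 0.0)], 300, bwm_plant,
                             bwm_sensor, ctrl, calibration_frames=CAL, seed=0)
        i0 = res.calibration_frames
        first = res.status[i0 : i0 + 150]
        second = res.status[i0 + 160 : i0 + 300]
        assert "L" in set(first)
        assert "H" in set(second)

    def test_non_increasing_schedule_rejected(self, bwm_plant, bwm_sensor, bwm_controller):
        with pytest.raises(ValueError):
            run_on_the_run([(100.0, 1.0), (100.0, 2.0)], 50, bwm_plant,
                           bwm_sensor, bwm_controller, calibration_frames=CAL)


class TestResultsFile:
    def test_write_read_round_trip(self, bwm_plant, bwm_sensor, bwm_controller, tmp_path):
        res = run_session(short_proto(), bwm_plant, bwm_sensor, bwm_controller)
        path = tmp_path / "session.txt"
        write_results(res, str(path))
        back = read_results(str(path))
        assert back.header["targets"] == "0,-5,5,0"
        assert float(back.header["bleach_r2"]) > 0.8
        np.testing.assert_array_equal(back.status, res.status)
        np.testing.assert_allclose(back.dff_pct, res.dff_pct, atol=1e-6)
        np.testing.assert_allclose(back.wavelength_nm, res.wavelength_nm, atol=1e-4)
        # analysis entry points work on re-read files
        assert back.step_bounds() == res.step_bounds()
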