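"""Signal synthesis: templates, calibration, the definitional DC/AC/R
contracts, and sensor corruption."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oxibench import (
    CalibrationCurve,
    DEFAULT_CURVE,
    SensorModel,
    SimSetting,
    apply_sensor_model,
    make_pulse_template,
    spo2_to_ratio,
    synthesize_optical_signal,
)
from oxibench.errors import ValidationError
from oxibench.virtual_oximeter import estimate_heart_rate


class TestPulseTemplate:
    def test_normalization(self, template):
        assert abs(template.samples.mean()) < 1e-12
        assert np.ptp(template.samples) == pytest.approx(1.0, abs=1e-12)

    def test_systolic_peak_in_first_half(self, template):
        assert np.argmax(template.samples) < template.samples.size / 2

    def test_periodic_continuity_at_wrap(self, template):
        jump = abs(template.samples[0] - template.samples[-1])
        typical_step = np.median(np.abs(np.diff(template.samples)))
        assert jump < 5 * typical_step + 1e-9

    def test_unknown_label_lists_available(self):
        with pytest.raises(ValidationError, match="child_nsr"):
            make_pulse_template("no_such_wave", 125)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValidationError, match="sample_rate"):
            make_pulse_template("child_nsr", 20)

    def test_first_two_harmonics_dominate(self, template):
        # the spectral AC extractor relies on the first two harmonics
        # carrying nearly all the peak-to-peak amplitude
        a = template.harmonic_amplitudes(6)
        assert a[0] > a[1] > a[2]
        assert (a[0] + a[1]) / a.sum() > 0.9


class TestCalibrationCurve:
    @pytest.mark.parametrize(
        "spo2, expected_r", [(95, 0.6), (85, 1.0), (65, 1.8)]
    )
    def test_default_linear_inversion(self, spo2, expected_r):
        assert spo2_to_ratio(spo2) == pytest.approx(expected_r, abs=1e-12)

    @given(st.floats(65, 95))
    def test_round_trip(self, s):
        r = DEFAULT_CURVE.ratio(s)
        assert DEFAULT_CURVE.spo2(r) == pytest.approx(s, abs=1e-9)

    def test_out_of_image_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            spo2_to_ratio(109.99, CalibrationCurve(r_min=0.5))

    def test_quadratic_curve_round_trip(self):
        curve = CalibrationCurve(intercept=112.0, slope=-20.0, quad=-3.0, r_min=0.3, r_max=2.5)
        for s in (65.0, 80.0, 95.0):
            assert curve.spo2(curve.ratio(s)) == pytest.approx(s, abs=1e-9)

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValidationError, match="decreasing"):
            CalibrationCurve(slope=-1.0, quad=5.0)


class TestSimSetting:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(t_pct=0.0), "t_pct"),
            (dict(mod_pct=-1.0), "mod_pct"),
            (dict(mod_pct=100.0), "mod_pct"),
            (dict(spo2_pct=0.0), "spo2_pct"),
            (dict(spo2_pct=101.0), "spo2_pct"),
            (dict(hr_bpm=0.0), "hr_bpm"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, field):
        base = dict(t_pct=1.98, mod_pct=1.1, spo2_pct=85, hr_bpm=120)
        base.update(kwargs)
        with pytest.raises(ValidationError, match=field):
            SimSetting(**base)


class TestSynthesis:
    def test_definitional_amplitudes_at_unity_ratio(self, template):
        # SpO2 85 -> R = 1, so both channels carry the same modulation depth
        sig = synthesize_optical_signal(
            SimSetting(4.49, 2.0, 85, 120), template=template
        )
        assert sig.ir.mean() == pytest.approx(4.49, rel=1e-3)
        assert np.ptp(sig.ir) == pytest.approx(0.0898, rel=1e-2)
        assert np.ptp(sig.red) == pytest.approx(0.0898, rel=1e-2)

    def test_cardiac_fundamental_forced_by_construction(self, template):
        sig = synthesize_optical_signal(
            SimSetting(0.39, 0.2, 65, 80), template=template
        )
        for channel in (sig.ir, sig.red):
            f0 = estimate_heart_rate(channel, sig.sample_rate)
            assert f0 == pytest.approx(80 / 60, rel=1e-3)

    def test_peak_to_peak_ratio_encodes_spo2(self, template):
        sig = synthesize_optical_signal(
            SimSetting(1.98, 1.1, 95, 130), template=template
        )
        assert np.ptp(sig.red) / np.ptp(sig.ir) == pytest.approx(0.6, rel=1e-6)

    def test_noiseless_intensities_positive(self, template):
        sig = synthesize_optical_signal(SimSetting(0.39, 2.0, 65, 80), template=template)
        assert (sig.ir > 0).all() and (sig.red > 0).all()

    def test_round_trip_fidelity_full_grid(self, template):
        # for every grid setting, DC, modulation amplitude and ratio-of-ratios
        # measured from the generated arrays match the commanded values;
        # amplitudes via least-squares fit of the known waveform, which is
        # exact for the noiseless synthesis model
        from oxibench import default_grid, enumerate_grid

        for setting in enumerate_grid(default_grid()):
            sig = synthesize_optical_signal(
                setting, template=template, duration=12.0
            )
            r_cmd = spo2_to_ratio(setting.spo2_pct)
            w = template.evaluate(sig.time * setting.hr_bpm / 60.0)
            wn = w - w.mean()
            for channel, depth in ((sig.ir, setting.mod_pct / 100.0),
                                   (sig.red, r_cmd * setting.mod_pct / 100.0)):
                dc = channel.mean()
                assert dc == pytest.approx(setting.t_pct, rel=1e-3)
                amp = np.dot(channel - dc, wn) / np.dot(wn, wn)
                assert amp == pytest.approx(setting.t_pct * depth, rel=1e-3)

    def test_red_modulation_depth_capped(self, template):
        # R * mod must stay below 100% of DC
        with pytest.raises(ValidationError, match="< 100"):
            synthesize_optical_signal(
                SimSetting(1.0, 60.0, 65, 80), template=template
            )


class TestSensorModel:
    def test_identity_sensor_is_noop(self, template):
        sig = synthesize_optical_signal(SimSetting(1.98, 1.1, 85, 120), template=template)
        out = apply_sensor_model(sig, SensorModel(sensor_id=1))
        np.testing.assert_array_equal(out.ir, sig.ir)
        np.testing.assert_array_equal(out.red, sig.red)

    def test_corruption_deterministic_under_seed(self, template):
        sig = synthesize_optical_signal(SimSetting(0.87, 0.6, 75, 100), template=template)
        sensor = SensorModel(sensor_id=1, noise_sigma=2e-4, rng_seed=7)
        a = apply_sensor_model(sig, sensor)
        b = apply_sensor_model(sig, sensor)
        np.testing.assert_array_equal(a.ir, b.ir)
        np.testing.assert_array_equal(a.red, b.red)

    def test_gain_scales_ac_preserves_dc(self, template):
        sig = synthesize_optical_signal(SimSetting(1.98, 1.1, 85, 120), template=template)
        out = apply_sensor_model(sig, SensorModel(sensor_id=1, gain_ir=1.1, gain_red=0.9))
        assert out.ir.mean() == pytest.approx(sig.ir.mean(), rel=1e-12)
        assert np.ptp(out.ir) == pytest.approx(1.1 * np.ptp(sig.ir), rel=1e-12)
        assert np.ptp(out.red) == pytest.approx(0.9 * np.ptp(sig.red), rel=1e-12)

    def test_injected_noise_level(self, template):
        # Monte-Carlo check: residual sd within 10% of the commanded sigma
        sig = synthesize_optical_signal(SimSetting(0.39, 0.2, 85, 120), template=template)
        out = apply_sensor_model(
            sig, SensorModel(sensor_id=1, noise_sigma=2e-4, rng_seed=3)
        )
        resid = np.concatenate([out.ir - sig.ir, out.red - sig.red])
        assert resid.std() == pytest.approx(2e-4, rel=0.10)
        assert abs(resid.mean()) < 5e-6

    def test_noise_level_independent_of_transmission(self, template):
        # constant detector noise floor: halving %T halves the AC-relative SNR
        sds = {}
        for t_pct in (4.0, 2.0):
            sig = synthesize_optical_signal(
                SimSetting(t_pct, 1.1, 85, 120), template=template
            )
            out = apply_sensor_model(
                sig, SensorModel(sensor_id=1, noise_sigma=2e-4, rng_seed=5)
            )
            sds[t_pct] = (out.ir - sig.ir).std()
        assert sds[4.0] == pytest.approx(sds[2.0], rel=0.05)
        snr_hi = 4.0 * 1.1 / sds[4.0]
        snr_lo = 2.0 * 1.1 / sds[2.0]
        assert snr_hi / snr_lo == pytest.approx(2.0, rel=0.05)

    def test_quantization_grid(self, template):
        sig = synthesize_optical_signal(SimSetting(1.98, 1.1, 85, 120), template=template)
        out = apply_sensor_model(
            sig, SensorModel(sensor_id=1, quantization_step=1e-3)
        )
        np.testing.assert_allclose(out.ir / 1e-3, np.round(out.ir / 1e-3), atol=1e-9)


def test_signal_frame_export(template):
    sig = synthesize_optical_signal(SimSetting(1.98, 1.1, 85, 120), template=template)
    frame = sig.to_frame()
    assert list(frame.columns) == ["time_s", "red", "ir"]
    assert len(frame) == sig.n_samples
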