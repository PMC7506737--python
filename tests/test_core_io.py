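"""Data model, file round trips, filtering, resampling and bias estimation."""

import numpy as np
import pytest
from scipy.signal import butter, freqz

from reachkin.core_io import (
    CalibrationError,
    ImuStream,
    SchemaError,
    SensorBias,
    SensorSet,
    TrialCondition,
    estimate_static_bias,
    lowpass_filter,
    read_sensor_set,
    resample_stream,
    write_sensor_set,
)


def _stream(site="hand", dur=2.0, accel_rate=100.0, gyro_rate=200.0, rng=None):
    rng = rng or np.random.default_rng(0)
    ta = np.arange(int(dur * accel_rate) + 1) / accel_rate
    tg = np.arange(int(dur * gyro_rate) + 1) / gyro_rate
    return ImuStream(
        site=site,
        t_accel=ta,
        accel=rng.normal(0, 1, (len(ta), 3)) + [0, 0, 9.81],
        t_gyro=tg,
        gyro=rng.normal(0, 0.01, (len(tg), 3)),
        accel_rate=accel_rate,
        gyro_rate=gyro_rate,
    )


def _sensor_set(rng=None):
    from reachkin.conventions import SENSOR_SITES

    rng = rng or np.random.default_rng(1)
    return SensorSet(
        streams={s: _stream(s, rng=rng) for s in SENSOR_SITES},
        condition=TrialCondition("AF", "BW", "Tab1", 2),
        side="left",
    )


class TestDataModel:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _s = _stream()
            ImuStream(site="hand", t_accel=_s.t_accel[::-1], accel=_s.accel,
                      t_gyro=_s.t_gyro, gyro=_s.gyro)

    def test_rate_consistency_enforced(self):
        s = _stream()
        with pytest.raises(ValueError, match="inconsistent"):
            ImuStream(site="hand", t_accel=s.t_accel, accel=s.accel,
                      t_gyro=s.t_gyro, gyro=s.gyro, gyro_rate=977.0)

    def test_block_masses_fixed(self):
        assert TrialCondition("AF", "BL", "Tab1").mass_kg == 0.108
        assert TrialCondition("AF", "BW", "Tab1").mass_kg == 0.490
        assert TrialCondition("AF", "BH", "Top4").mass_kg == 1.008
        with pytest.raises(ValueError):
            TrialCondition("AF", "BX", "Tab1")

    def test_gyro_bias_sanity_bound(self):
        with pytest.raises(CalibrationError):
            SensorBias(site="hand", accel_bias=np.zeros(3), gyro_bias=[0.3, 0, 0])


class TestRoundTrip:
    def test_write_read_bit_exact(self, tmp_path):
        sset = _sensor_set()
        write_sensor_set(tmp_path / "rec", sset)
        back = read_sensor_set(tmp_path / "rec")
        for site, st in sset.streams.items():
            np.testing.assert_array_equal(back.streams[site].accel, st.accel)
            np.testing.assert_array_equal(back.streams[site].gyro, st.gyro)
            np.testing.assert_array_equal(back.streams[site].t_gyro, st.t_gyro)
        assert back.condition == sset.condition

    def test_missing_stream_named_in_error(self, tmp_path):
        sset = _sensor_set()
        write_sensor_set(tmp_path / "rec", sset)
        (tmp_path / "rec" / "imu_hand.csv").unlink()
        with pytest.raises(SchemaError, match="hand"):
            read_sensor_set(tmp_path / "rec")

    def test_incomplete_sensor_set_rejected(self):
        sset = _sensor_set()
        streams = dict(sset.streams)
        del streams["sternum"]
        with pytest.raises(SchemaError, match="sternum"):
            SensorSet(streams=streams)


class TestLowpass:
    def test_constant_signal_preserved(self):
        s = _stream()
        s.accel[:] = [1.5, -2.0, 9.81]
        s.gyro[:] = 0.123
        out = lowpass_filter(s, 10.0)
        np.testing.assert_allclose(out.accel, s.accel, atol=1e-9)
        np.testing.assert_allclose(out.gyro, s.gyro, atol=1e-9)
        np.testing.assert_array_equal(out.t_gyro, s.t_gyro)

    def test_stopband_attenuation_matches_filter_design(self):
        # 40 Hz tone sampled at 200 Hz, cutoff 10 Hz: gain is |H|^2 of the
        # order-2 design because of the forward-backward pass
        tg = np.arange(4001) / 200.0
        s = ImuStream(
            site="hand",
            t_accel=tg[::2], accel=np.zeros((2001, 3)),
            t_gyro=tg, gyro=np.column_stack([np.sin(2 * np.pi * 40 * tg)] * 3),
        )
        out = lowpass_filter(s, 10.0)
        mid = slice(1000, 3000)
        measured = np.abs(out.gyro[mid, 0]).max()
        b, a = butter(2, 10.0, fs=200.0)
        _, h = freqz(b, a, worN=[40.0], fs=200.0)
        analytic = float(np.abs(h[0]) ** 2)
        assert measured < 0.05
        assert abs(measured - analytic) < 0.01 * 1.0  # within 1% of unit input

    def test_idempotent_for_band_limited_signal(self):
        tg = np.arange(2001) / 200.0
        sig = np.sin(2 * np.pi * 2.0 * tg)  # well below cutoff/2
        s = ImuStream(site="hand", t_accel=tg[::2], accel=np.zeros((1001, 3)),
                      t_gyro=tg, gyro=np.column_stack([sig] * 3))
        once = lowpass_filter(s, 10.0)
        twice = lowpass_filter(once, 10.0)
        mid = slice(200, 1800)
        ratio = np.abs(twice.gyro[mid, 0]).max() / np.abs(once.gyro[mid, 0]).max()
        assert abs(ratio - 1.0) < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(_stream(), 60.0)

    def test_default_cutoff_is_10_hz(self):
        import inspect

        assert inspect.signature(lowpass_filter).parameters["cutoff"].default == 10.0


class TestResample:
    def test_native_rate_is_identity(self):
        s = _stream(accel_rate=100.0, gyro_rate=100.0)
        s = ImuStream(site="hand", t_accel=s.t_gyro, accel=s.gyro + 5, t_gyro=s.t_gyro,
                      gyro=s.gyro, accel_rate=100.0, gyro_rate=100.0)
        out = resample_stream(s, 100.0)
        np.testing.assert_allclose(out.gyro, s.gyro, atol=1e-12)

    def test_upsampled_ramp_midpoints_are_means(self):
        tg = np.arange(101) / 100.0
        ramp = np.column_stack([2.0 * tg, -tg, tg + 1])
        s = ImuStream(site="hand", t_accel=tg, accel=ramp, t_gyro=tg, gyro=ramp,
                      accel_rate=100.0, gyro_rate=100.0)
        out = resample_stream(s, 200.0)
        mids = out.gyro[1:-1:2]
        means = 0.5 * (ramp[:-1] + ramp[1:])
        np.testing.assert_allclose(mids, means[: len(mids)], atol=1e-12)

    def test_mixed_rates_unified(self):
        out = resample_stream(_stream(), 100.0)
        assert out.aligned
        assert len(out.t_accel) == len(out.t_gyro)
        assert out.accel_rate == out.gyro_rate == 100.0

    def test_empty_stream_rejected(self):
        s = _stream()
        empty = ImuStream(site="hand", t_accel=np.empty(0), accel=np.empty((0, 3)),
                          t_gyro=s.t_gyro, gyro=s.gyro)
        with pytest.raises(ValueError, match="empty"):
            resample_stream(empty, 100.0)


def _box_segments(gyro_bias, accel_bias, noise_sd=0.0, dur=5.0, rate=100.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(dur * rate) + 1
    t = np.arange(n) / rate
    dirs = {"+x": [9.81, 0, 0], "-x": [-9.81, 0, 0], "+y": [0, 9.81, 0],
            "-y": [0, -9.81, 0], "+z": [0, 0, 9.81], "-z": [0, 0, -9.81]}
    segs = {}
    for label, g in dirs.items():
        accel = np.tile(np.asarray(g, float) + accel_bias, (n, 1))
        gyro = np.tile(np.asarray(gyro_bias, float), (n, 1))
        if noise_sd:
            gyro = gyro + rng.normal(0, noise_sd, gyro.shape)
        segs[label] = ImuStream(site="hand", t_accel=t, accel=accel, t_gyro=t, gyro=gyro,
                                accel_rate=rate, gyro_rate=rate)
    return segs


class TestStaticBias:
    def test_gyro_bias_recovered_exactly(self):
        bias = np.array([0.01, -0.02, 0.005])
        out = estimate_static_bias(_box_segments(bias, np.zeros(3)))
        np.testing.assert_allclose(out.gyro_bias, bias, atol=1e-9)

    def test_accel_bias_recovered_exactly(self):
        bias = np.array([0.1, 0.0, -0.2])
        out = estimate_static_bias(_box_segments(np.zeros(3), bias))
        np.testing.assert_allclose(out.accel_bias, bias, atol=1e-9)

    def test_correction_zeroes_static_gyro(self):
        bias = np.array([0.03, -0.01, 0.02])
        segs = _box_segments(bias, np.zeros(3))
        est = estimate_static_bias(segs)
        corrected = est.apply(segs["+z"])
        assert np.abs(corrected.gyro.mean(axis=0)).max() < 1e-6

    def test_noisy_recovery_within_statistical_limit(self):
        # white noise sd 0.02 rad/s, 5 s segments: RMS recovery error over
        # seeds should track sigma/sqrt(n_total)
        sd, true = 0.02, np.array([0.004, -0.006, 0.002])
        errs = []
        for seed in range(100):
            est = estimate_static_bias(_box_segments(true, np.zeros(3), noise_sd=sd, seed=seed))
            errs.append(est.gyro_bias - true)
        n_total = 6 * 501
        rms = np.sqrt(np.mean(np.square(errs)))
        assert rms < 1.5 * sd / np.sqrt(n_total)
        assert np.abs(errs).max() < 5 * sd / np.sqrt(n_total)

    def test_too_few_orientations_rejected(self):
        segs = _box_segments(np.zeros(3), np.zeros(3))
        segs.pop("+x")
        with pytest.raises(CalibrationError, match="6"):
            estimate_static_bias(segs)
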