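"""Signal-processing stages: filters, normalisation, envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

import ecodec as ec
from ecodec.errors import ParameterError


def welch_band_fraction(x, rate, low, high):
    f, p = sps.welch(x, fs=rate, nperseg=min(1 << 14, len(x)))
    total = np.trapezoid(p, f)
    sel = (f >= low) & (f <= high)
    return np.trapezoid(p[sel], f[sel]) / total


class TestDownsample:
    def test_dc_preserved(self):
        out = ec.downsample(np.full(40000, 3.0), 4000, 500)
        assert out.shape == (5000,)
        np.testing.assert_allclose(out, 3.0, atol=1e-9)

    def test_passband_sinusoid_amplitude_kept(self, rng):
        t = np.arange(0, 10, 1 / 4000)
        x = np.sin(2 * np.pi * 10 * t)
        y = ec.downsample(x, 4000, 500)
        # FFT peak amplitude of output vs input
        amp = 2 * np.abs(np.fft.rfft(y)) / len(y)
        f = np.fft.rfftfreq(len(y), 1 / 500)
        peak_f = f[np.argmax(amp)]
        assert peak_f == pytest.approx(10.0, abs=0.1)
        assert amp.max() == pytest.approx(1.0, rel=0.01)

    def test_above_nyquist_component_removed(self):
        t = np.arange(0, 10, 1 / 4000)
        x = np.sin(2 * np.pi * 300 * t)
        y = ec.downsample(x, 4000, 500)
        assert np.sqrt(np.mean(y ** 2)) < 0.05 * np.sqrt(np.mean(x ** 2))

    def test_upsampling_rejected(self):
        with pytest.raises(ParameterError):
            ec.downsample(np.zeros(100), 500, 4000)


class TestCommonAverageReference:
    def test_hand_computed_two_channels(self):
        x = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        out = ec.common_average_reference(x)
        np.testing.assert_allclose(out, [[-1, -1, -1], [1, 1, 1]])

    def test_channel_mean_identically_zero(self, rng):
        x = rng.standard_normal((7, 500)) * 40 + 3
        out = ec.common_average_reference(x)
        assert np.abs(out.mean(axis=0)).max() < 1e-12

    def test_identical_channels_become_zero(self):
        x = np.tile(np.sin(np.linspace(0, 5, 100)), (4, 1))
        np.testing.assert_allclose(ec.common_average_reference(x), 0, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ParameterError):
            ec.common_average_reference(np.zeros((1, 100)))


class TestBandpass:
    def test_white_noise_power_concentrates_in_band(self, rng):
        x = rng.standard_normal(100 * 500)
        y = ec.bandpass(x, 1.5, 4.0, 500)
        assert welch_band_fraction(y, 500, 1.0, 5.0) >= 0.85

    def test_band_center_amplitude_near_unity(self):
        f0 = np.sqrt(50 * 90)  # geometric centre of the high-gamma band
        t = np.arange(0, 20, 1 / 500)
        x = np.sin(2 * np.pi * f0 * t)
        y = ec.bandpass(x, 50, 90, 500)
        ratio = y[2000:-2000].std() / x[2000:-2000].std()
        assert 0.95 <= ratio <= 1.0

    def test_zero_phase(self):
        t = np.arange(0, 20, 1 / 500)
        f0 = np.sqrt(14 * 20)
        x = np.sin(2 * np.pi * f0 * t)
        y = ec.bandpass(x, 14, 20, 500)
        ys, xs = y[1000:-1000], x[1000:-1000]
        lags = sps.correlation_lags(len(ys), len(xs))
        xc = sps.correlate(ys, xs)
        assert lags[np.argmax(xc)] == 0

    def test_dc_removed(self):
        y = ec.bandpass(np.full(5000, 5.0), 4, 8, 500)
        assert abs(y[500:-500].mean()) < 1e-3

    def test_edge_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            ec.bandpass(np.zeros(100), 50, 250, 500)


class TestCausalZscore:
    def test_constant_signal_gives_zeros_and_warns(self):
        with pytest.warns(RuntimeWarning):
            out, valid_from = ec.causal_zscore(np.full(2000, 4.2), 500)
        np.testing.assert_array_equal(out, 0.0)
        assert valid_from == 1.0

    def test_stationary_noise_statistics(self, rng):
        x = rng.standard_normal(60 * 500)
        out, _ = ec.causal_zscore(x, 500)
        valid = out[500:]
        assert abs(valid.mean()) < 0.05
        assert 0.9 < valid.std() < 1.1

    def test_step_normalised_by_pre_step_window(self, rng):
        # brute-force oracle: window mean/SD computed with explicit loops
        x = np.concatenate([rng.standard_normal(800), np.full(400, 10.0)])
        out, _ = ec.causal_zscore(x, 500, window=1.0)
        t0 = 800
        win = x[t0 - 500:t0]
        expected = (10.0 - win.mean()) / win.std()
        assert out[t0] == pytest.approx(expected, rel=1e-10)

    def test_warmup_samples_are_zero(self, rng):
        out, _ = ec.causal_zscore(rng.standard_normal(1000), 500)
        np.testing.assert_array_equal(out[:500], 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(cut=st.integers(min_value=700, max_value=1500))
    def test_truncation_does_not_change_past(self, cut):
        # causality: output at or before t never depends on samples after t
        x = np.random.default_rng(7).standard_normal(1600)
        full, _ = ec.causal_zscore(x, 500)
        trunc, _ = ec.causal_zscore(x[:cut], 500)
        np.testing.assert_array_equal(full[:cut], trunc)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            ec.causal_zscore(np.zeros(400), 500, window=1.0)


class TestEnvelopeSmooth:
    def test_unit_dc_gain(self):
        out = ec.envelope_smooth(np.full(1000, 2.0), 500, rectify=False)
        np.testing.assert_allclose(out, 2.0, atol=1e-12)

    def test_impulse_response_is_kernel_at_impulse(self):
        x = np.zeros(501)
        x[250] = 1.0
        out = ec.envelope_smooth(x, 500, rectify=False)
        from ecodec.preprocess import gaussian_kernel
        k = gaussian_kernel(500)
        assert np.argmax(out) == 250
        np.testing.assert_allclose(out[250 - 25:250 + 26], k, atol=1e-15)

    def test_square_wave_rectifies_to_unity(self):
        t = np.arange(0, 4, 1 / 500)
        x = np.sign(np.sin(2 * np.pi * 50 * t))
        x[x == 0] = 1.0
        out = ec.envelope_smooth(x, 500, rectify=True)
        assert np.abs(out[100:-100] - 1.0).max() < 1e-6

    def test_homogeneity_degree_one(self, rng):
        x = rng.standard_normal(800)
        a = ec.envelope_smooth(2 * x, 500)
        b = 2 * ec.envelope_smooth(x, 500)
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestEmgEnvelope:
    def test_rectified_sine_mean(self):
        # analytic oracle: mean of |A sin| is 2A/pi
        A = 3.0
        t = np.arange(0, 20, 1 / 2000)
        emg = A * np.sin(2 * np.pi * 100 * t)
        cfg = ec.default_config()
        env = ec.emg_envelope(emg, 2000, cfg).activity[0]
        mid = env[len(env) // 4: -len(env) // 4]
        assert np.median(mid) == pytest.approx(2 * A / np.pi, rel=0.05)

    def test_zero_input_zero_envelope(self):
        env = ec.emg_envelope(np.zeros((2, 8000)), 2000, ec.default_config())
        np.testing.assert_array_equal(env.activity, 0.0)

    def test_nonnegative_and_homogeneous(self, rng):
        cfg = ec.default_config()
        x = rng.standard_normal((2, 8000))
        env = ec.emg_envelope(x, 2000, cfg).activity
        assert (env >= 0).all()
        env2 = ec.emg_envelope(2 * x, 2000, cfg).activity
        np.testing.assert_allclose(env2, 2 * env, rtol=1e-9, atol=1e-12)


class TestExtractBandSources:
    def test_source_count_and_index_bijection(self, small_pipeline):
        src = small_pipeline["sources"]
        session = small_pipeline["session"]
        assert src.n_sources == session.n_channels * 7 == 112
        assert len(set(src.index)) == src.n_sources
        chans = {ch for ch, _ in src.index}
        bands = {b for _, b in src.index}
        assert chans == set(session.channel_names)
        assert len(bands) == 7

    def test_grid_of_fifteen_channels_gives_105(self):
        spec = ec.make_subject_spec("A", seed=0)
        assert spec.n_channels * 7 == 105

    def test_session_shorter_than_window_errors(self, rng):
        n = int(0.8 * 2000)  # shorter than the 1 s z-score window
        sess = ec.RecordingSession(
            ecog=rng.standard_normal((2, n)), emg=rng.standard_normal((1, n)),
            rate_ecog=2000, rate_emg=2000, events=[],
            layout=ec.ElectrodeLayout(1, 2, {"a": 1, "b": 2}),
            channel_names=["a", "b"], muscle_names=["m"])
        with pytest.raises(ParameterError, match="insufficient duration"):
            ec.extract_band_sources(sess, ec.default_config())
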