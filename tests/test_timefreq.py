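import numpy as np
import pytest

from hgalpha import timefreq as tfmod
from hgalpha.containers import EpochedRecording
from hgalpha.timefreq import TFPower, WaveletConfig, band_window_power, \
    baseline_db, morlet_power, offset_locked_power, wavelet_cycles

from conftest import sinusoid_epochs


CFG = WaveletConfig()


def test_cycle_schedule_is_linear_then_flat():
    np.testing.assert_allclose(
        wavelet_cycles(np.array([2.0, 16.0, 30.0, 40.0, 180.0]), CFG),
        [3.0, 7.5, 12.0, 12.0, 12.0])


def test_frequency_grids_have_paper_resolution():
    assert CFG.low_freqs().size == 141 and CFG.high_freqs().size == 141
    assert CFG.low_freqs()[1] - CFG.low_freqs()[0] == pytest.approx(0.2)


class TestMorletPower:
    def test_stationary_sinusoid_gives_constant_ridge(self):
        rec = sinusoid_epochs(10.0, 1.0, n_trials=4)
        tf = morlet_power(rec, CFG, freqs=np.arange(5.0, 15.2, 0.2))
        ridge = tf.frequencies[np.argmax(tf.power[0].mean(axis=1))]
        assert ridge == pytest.approx(10.0)
        row = tf.power[0, np.argmax(tf.power[0].mean(axis=1))]
        assert row.std() / row.mean() < 0.01

    def test_amplitude_step_quadruples_power(self):
        env = lambda t: np.where(t >= 0, 2.0, 1.0)
        rec = sinusoid_epochs(10.0, env, n_trials=3)
        tf = morlet_power(rec, CFG, freqs=np.array([10.0]))
        pre = band_window_power(tf, (10, 10), (-1.0, -0.5))
        post = band_window_power(tf, (10, 10), (0.5, 1.0))
        assert post[0] / pre[0] == pytest.approx(4.0, rel=0.02)

    def test_zero_input_gives_zero_power(self):
        rec = sinusoid_epochs(10.0, 0.0, n_trials=2)
        tf = morlet_power(rec, CFG, freqs=np.array([8.0, 20.0]))
        np.testing.assert_allclose(tf.power, 0.0, atol=1e-20)

    def test_edge_violation_names_the_frequency(self):
        rec = sinusoid_epochs(10.0, 1.0, n_trials=2, span=(-0.8, 1.4))
        with pytest.raises(ValueError, match="2 Hz"):
            morlet_power(rec, CFG)

    def test_output_grid_alignment(self):
        rec = sinusoid_epochs(10.0, 1.0, n_trials=2)
        tf = morlet_power(rec, CFG, freqs=np.array([10.0]))
        assert tf.times.size == 181  # -0.6..1.2 at 10 ms, both ends
        assert 0.0 in tf.times

    def test_white_noise_power_is_flat_across_frequency(self):
        # unit-energy wavelets: E|c|^2 equals the noise variance at every f
        rng = np.random.default_rng(0)
        data = rng.standard_normal((30, 1, 7800))
        times = -1.5 + np.arange(7800) / 1000.0
        rec = EpochedRecording(data, 1000.0, times,
                               np.array(["x"] * 30), np.array(["c0"]))
        tf = morlet_power(rec, CFG, freqs=np.arange(4.0, 30.0, 2.0))
        mean_by_f = tf.power[0].mean(axis=1)
        assert mean_by_f.max() / mean_by_f.min() < 1.3
        assert abs(mean_by_f.mean() - 1.0) < 0.15

    def test_temporal_resolution_tracks_cycles_over_frequency(self):
        # ridge width around an amplitude impulse scales with cycles/f
        widths = {}
        for f0 in (5.0, 20.0):
            n = 7800
            times = -1.5 + np.arange(n) / 1000.0
            x = np.zeros(n)
            x[np.argmin(np.abs(times - 0.3))] = 1.0
            rec = EpochedRecording(np.tile(x, (2, 1, 1)), 1000.0, times,
                                   np.array(["x", "x"]), np.array(["c0"]))
            tf = morlet_power(rec, CFG, freqs=np.array([f0]))
            row = tf.power[0, 0]
            half = row >= 0.5 * row.max()
            widths[f0] = half.sum() * CFG.time_step
        cyc = wavelet_cycles(np.array([5.0, 20.0]), CFG)
        expected_ratio = (cyc[0] / 5.0) / (cyc[1] / 20.0)
        assert widths[5.0] / widths[20.0] == pytest.approx(expected_ratio,
                                                           rel=0.35)


class TestBaselineDb:
    def make_tf(self, power):
        f = np.array([8.0])
        t = np.arange(-0.6, 1.21, 0.01)
        return TFPower(power * np.ones((1, 1, t.size)), f, t,
                       np.array(["c0"]), "raw")

    def test_flat_power_maps_to_zero_db(self):
        db = baseline_db(self.make_tf(5.0))
        np.testing.assert_allclose(db.power, 0.0, atol=1e-12)

    def test_tenfold_power_is_plus_ten_db(self):
        tf = self.make_tf(1.0)
        tf.power[..., tf.times >= 0] = 10.0
        db = baseline_db(tf)
        assert db.power[0, 0, -1] == pytest.approx(10.0)

    def test_half_amplitude_is_minus_six_db(self):
        tf = self.make_tf(1.0)
        tf.power[..., tf.times >= 0] = 0.25  # amplitude halved -> power /4
        db = baseline_db(tf)
        assert db.power[0, 0, -1] == pytest.approx(-6.0206, abs=1e-3)

    def test_correction_is_invertible(self):
        rng = np.random.default_rng(1)
        t = np.arange(-0.6, 1.21, 0.01)
        raw = TFPower(rng.uniform(0.5, 2.0, (2, 3, t.size)),
                      np.array([8.0, 9.0, 10.0]), t,
                      np.array(["a", "b"]), "raw")
        db = baseline_db(raw)
        sel = (t >= -0.6) & (t <= -0.1 + 1e-9)
        base = raw.power[..., sel].mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(10 ** (db.power / 10) * base, raw.power,
                                   rtol=1e-10)

    def test_double_conversion_rejected(self):
        db = baseline_db(self.make_tf(1.0))
        with pytest.raises(ValueError):
            baseline_db(db)


class TestBandWindowExtraction:
    def test_uniform_field_passes_through(self):
        t = np.arange(-0.6, 1.21, 0.01)
        tf = TFPower(np.full((1, 16, t.size), 3.0),
                     np.arange(7.0, 10.2, 0.2), t, np.array(["c0"]), "dB")
        assert band_window_power(tf, (7, 10), (0.5, 1.2))[0] == pytest.approx(3.0)

    def test_grid_arithmetic_for_alpha_band_and_window(self):
        low = CFG.low_freqs()
        assert ((low >= 7 - 1e-9) & (low <= 10 + 1e-9)).sum() == 16
        t = tfmod._out_times(CFG.analysis_window, CFG.time_step)
        assert ((t >= 0.5 - 1e-9) & (t <= 1.2 + 1e-9)).sum() == 71

    def test_empty_selection_rejected(self):
        t = np.arange(-0.6, 1.21, 0.01)
        tf = TFPower(np.ones((1, 1, t.size)), np.array([8.0]), t,
                     np.array(["c0"]), "dB")
        with pytest.raises(ValueError):
            band_window_power(tf, (50, 60), (0.5, 1.2))


class TestOffsetLocked:
    def suppressed_epochs(self, suppression, durations, noise=0.01):
        def env_factory(d):
            return lambda t: np.where((t >= 0) & (t < d),
                                      1.0 - suppression, 1.0)
        trials, times = [], None
        rng = np.random.default_rng(0)
        sr = 1000.0
        n = int(7.8 * sr)
        times = -1.5 + np.arange(n) / sr
        for i, d in enumerate(durations):
            x = env_factory(d)(times) * np.sin(
                2 * np.pi * 8.0 * times + rng.uniform(0, 2 * np.pi))
            trials.append(x + noise * rng.standard_normal(n))
        data = np.stack(trials)[:, None, :]
        return EpochedRecording(data, sr, times,
                                np.array(["clear"] * len(durations)),
                                np.array(["c0"]),
                                sentence_durations=np.array(durations))

    def test_sustained_suppression_visible_before_offset(self):
        rec = self.suppressed_epochs(0.5, [2.5, 3.0, 3.5, 4.0])
        db = offset_locked_power(rec)
        assert db[0] == pytest.approx(20 * np.log10(0.5), abs=0.8)

    def test_no_suppression_gives_zero_db(self):
        rec = self.suppressed_epochs(0.0, [2.5, 3.0, 3.5, 4.0])
        assert abs(offset_locked_power(rec)[0]) < 0.3

    def test_short_sentences_are_excluded(self):
        rec = self.suppressed_epochs(0.5, [0.8, 0.9, 3.0, 3.5])
        with pytest.warns(UserWarning, match="shorter"):
            db = offset_locked_power(rec)
        assert np.isfinite(db[0])

    def test_all_short_sentences_is_an_error(self):
        rec = self.suppressed_epochs(0.5, [0.8, 0.9, 1.0, 1.1])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no trials"):
                offset_locked_power(rec)
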