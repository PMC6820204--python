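import numpy as np
import pytest
from scipy import signal as sps

from hgalpha.simulate import SimulationParams, simulate_dataset, \
    spectral_background
from hgalpha import timefreq

from conftest import tiny_params


def welch_loglog_slope(x, sample_rate, f_range=(2.0, 180.0)):
    f, p = sps.welch(x, sample_rate, nperseg=4096)
    sel = (f >= f_range[0]) & (f <= f_range[1])
    return np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]


class TestSpectralBackground:
    def test_white_noise_has_flat_spectrum(self):
        x = spectral_background(0.0, 60000, 1000.0, seed=0)
        assert abs(welch_loglog_slope(x, 1000.0)) < 0.1

    def test_chi2_slope_recovered(self):
        slopes = [welch_loglog_slope(
            spectral_background(2.0, 60000, 1000.0, seed=s), 1000.0)
            for s in range(20)]
        assert abs(np.mean(slopes) + 2.0) < 0.15

    def test_variance_scales_with_amplitude(self):
        a = spectral_background(2.0, 20000, 1000.0, seed=1, amplitude=1.0)
        b = spectral_background(2.0, 20000, 1000.0, seed=1, amplitude=3.0)
        assert np.isfinite(a).all()
        np.testing.assert_allclose(b, 3.0 * a)

    def test_psd_anchored_at_alpha_frequency(self):
        # changing the exponent rotates the spectrum about 8 Hz
        est = {}
        for chi in (1.0, 2.5):
            acc = []
            for s in range(10):
                x = spectral_background(chi, 60000, 1000.0, seed=s)
                f, p = sps.welch(x, 1000.0, nperseg=8192)
                acc.append(np.interp(8.0, f, p))
            est[chi] = np.mean(acc)
        assert abs(est[1.0] / est[2.5] - 1.0) < 0.1

    def test_negative_chi_rejected(self):
        with pytest.raises(ValueError):
            spectral_background(-1.0, 1000, 1000.0, seed=0)


class TestGeometry:
    def test_distances_are_euclidean_norms_to_alhg_centroid(self, tiny_dataset):
        cs = tiny_dataset.contacts
        d = cs.distance_to_alhg_centroid()
        for h in np.unique(cs.hemisphere_id):
            sub = cs.hemisphere(h)
            centroid = sub.coordinates[sub.zone == "alHG"].mean(axis=0)
            expected = np.linalg.norm(sub.coordinates - centroid, axis=1)
            np.testing.assert_allclose(d[cs.hemisphere_id == h], expected)

    def test_zone_counts_match_params(self, tiny_dataset):
        cs = tiny_dataset.contacts
        p = tiny_dataset.params
        for h in range(p.n_hemispheres):
            sub = cs.hemisphere(h)
            assert (sub.zone == "pmHG").sum() == p.n_pmhg
            assert (sub.zone == "alHG").sum() == p.n_alhg
            assert (sub.zone == "STP_STG_other").sum() == p.n_other


class TestSimulateDataset:
    def test_epoch_axes_and_labels(self, tiny_dataset):
        rec = tiny_dataset.sentence_epochs[0]
        assert rec.times[0] == pytest.approx(-1.5)
        assert rec.times[-1] == pytest.approx(6.3 - 1 / rec.sample_rate)
        assert not np.isnan(rec.data).any()
        assert (rec.conditions == "clear").sum() == \
            (rec.conditions == "vocoded").sum()
        lo, hi = tiny_dataset.params.sentence_duration_range
        assert np.all((rec.sentence_durations >= lo)
                      & (rec.sentence_durations <= hi))

    def test_seed_reproducibility_is_bit_exact(self):
        a = simulate_dataset(tiny_params(seed=11))
        b = simulate_dataset(tiny_params(seed=11))
        np.testing.assert_array_equal(a.sentence_epochs[0].data,
                                      b.sentence_epochs[0].data)
        np.testing.assert_array_equal(a.click_epochs[1].data,
                                      b.click_epochs[1].data)
        np.testing.assert_array_equal(a.contacts.coordinates,
                                      b.contacts.coordinates)

    @pytest.mark.parametrize("bad", [
        dict(suppression_clear=0.2, suppression_vocoded=0.5),
        dict(suppression_clear=1.0),
        dict(click_latency_pmHG=0.025),
        dict(click_latency_alHG=0.015),
        dict(n_trials_per_condition=0),
        dict(chi=-0.5),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_dataset(tiny_params(**bad))


@pytest.fixture(scope="module")
def suppression_measurements():
    """Per-contact measured vs generative-law alpha suppression, 5 seeds."""
    rows = []
    for seed in range(5):
        p = SimulationParams(
            n_hemispheres=1, n_trials_per_condition=10,
            n_click_trials_per_rate=2, n_pmhg=2, n_alhg=3, n_other=5,
            suppression_clear=0.75, suppression_vocoded=0.75,
            alpha_trial_cv=0.0, chi_stim_delta_alHG=0.0, seed=100 + seed)
        ds = simulate_dataset(p)
        rec = ds.sentence_epochs[0]
        cfg = timefreq.WaveletConfig()
        low = cfg.low_freqs()
        freqs = low[(low >= 7) & (low <= 10 + 1e-9)]
        tf = timefreq.morlet_power(rec, cfg, freqs=freqs)
        db = timefreq.baseline_db(tf)
        measured = timefreq.band_window_power(db, (7, 10), (0.5, 1.2))
        d = ds.contacts.distance_to_alhg_centroid()
        predicted = 20 * np.log10(
            1 - 0.75 * np.exp(-d / p.spatial_decay_lambda))
        rows.append((d, measured, predicted))
    return rows


class TestSuppressionCalibration:
    """The measured alpha suppression should track the generative law
    20*log10(1 - s * exp(-d/lambda)) and weaken monotonically with distance."""

    def test_alpha_suppression_matches_generative_law(
            self, suppression_measurements):
        err = np.concatenate([m - p for _, m, p in suppression_measurements])
        assert abs(err.mean()) < 1.0

    def test_suppression_magnitude_decays_with_distance(
            self, suppression_measurements):
        d = np.concatenate([r[0] for r in suppression_measurements])
        m = np.concatenate([r[1] for r in suppression_measurements])
        # suppression is negative dB; farther contacts are less suppressed
        slope = np.polyfit(d, m, 1)[0]
        assert slope > 0
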