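"""Notch/decimation preprocessing, RMS normalization, Morlet decomposition."""

import numpy as np
import pytest

from betarec.spectral import (
    baseline_normalize,
    default_freqs,
    morlet_tfr,
    preprocess,
    tfr_stack,
)


def tone(freq, fs, dur_s, amplitude=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def fft_power_at(x, fs, freq):
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    return spec[np.argmin(np.abs(f - freq))]


class TestPreprocess:
    def test_notch_attenuates_50hz_by_20db(self):
        x = tone(50, 1000, 4)
        y = preprocess(x, 1000, (50.0,), 1000)
        ratio = fft_power_at(y, 1000, 50) / fft_power_at(x, 1000, 50)
        assert 10 * np.log10(ratio) < -20

    def test_passband_preserved_within_1db(self):
        x = tone(12, 1000, 4)
        y = preprocess(x, 1000, (50.0, 100.0, 150.0), 1000)
        ratio = fft_power_at(y, 1000, 12) / fft_power_at(x, 1000, 12)
        assert abs(10 * np.log10(ratio)) < 1

    def test_identity_without_notch_or_resample(self):
        x = tone(17, 1000, 2)
        assert np.allclose(preprocess(x, 1000, (), 1000), x)

    def test_decimation_preserves_low_frequency_content(self):
        x = tone(12, 30_000, 2)
        y = preprocess(x, 30_000, (), 1000)
        assert len(y) == 2000
        # 12 Hz tone survives with amplitude close to 1
        assert np.max(np.abs(y[500:1500])) == pytest.approx(1.0, abs=0.05)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros(100), 500, (), 1000)
        with pytest.raises(ValueError):
            preprocess(np.zeros(100), 1000, (600.0,), 1000)


class TestBaselineNormalize:
    def test_constant_baseline(self):
        x = np.arange(10.0)
        assert np.allclose(baseline_normalize(x, np.full(100, 2.0)), x / 2)

    def test_sine_baseline_rms(self):
        a = 3.0
        baseline = tone(10, 1000, 1, amplitude=a)
        x = np.ones(50)
        assert np.allclose(
            baseline_normalize(x, baseline), x / (a / np.sqrt(2)), rtol=1e-3
        )

    def test_normalized_baseline_has_unit_rms(self, rng):
        baseline = rng.normal(0, 5, 1000)
        out = baseline_normalize(baseline, baseline)
        assert np.sqrt(np.mean(out**2)) == pytest.approx(1.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            baseline_normalize(np.ones(10), np.zeros(100))


class TestMorletTFR:
    @pytest.mark.parametrize("n_cycles", [5.0, 7.0])
    def test_sine_peaks_at_its_frequency(self, n_cycles):
        x = tone(12, 1000, 3)
        tfr = morlet_tfr(x, 1000, np.arange(8.0, 31.0), n_cycles=n_cycles)
        row_means = tfr.power[:, tfr.valid.all(axis=0)].mean(axis=1)
        assert tfr.freqs[np.argmax(row_means)] == 12.0

    def test_zero_signal_zero_power(self):
        tfr = morlet_tfr(np.zeros(2000), 1000, np.arange(8.0, 20.0))
        assert np.allclose(tfr.power, 0)

    @pytest.mark.parametrize("n_cycles", [5.0, 7.0])
    def test_two_tone_resolved(self, n_cycles):
        x = tone(10, 1000, 3) + tone(40, 1000, 3)
        tfr = morlet_tfr(x, 1000, np.arange(8.0, 51.0), n_cycles=n_cycles)
        rm = tfr.power[:, tfr.valid.all(axis=0)].mean(axis=1)
        peaks = [
            i
            for i in range(1, len(rm) - 1)
            if rm[i] > rm[i - 1] and rm[i] > rm[i + 1]
        ]
        assert {10.0, 40.0} <= {tfr.freqs[i] for i in peaks}

    def test_quadratic_power_scaling(self):
        x = tone(15, 1000, 2)
        a = morlet_tfr(x, 1000, np.arange(10.0, 21.0))
        b = morlet_tfr(2 * x, 1000, np.arange(10.0, 21.0))
        assert np.allclose(b.power, 4 * a.power)

    def test_stationary_sine_power_flat_over_valid_region(self):
        x = tone(20, 1000, 4)
        tfr = morlet_tfr(x, 1000, np.arange(18.0, 23.0))
        band = tfr.power[:, tfr.valid.all(axis=0)].sum(axis=0)
        assert band.max() / band.min() < 1.05

    def test_default_grid_is_8_to_60(self):
        assert len(default_freqs()) == 53
        assert default_freqs()[0] == 8.0 and default_freqs()[-1] == 60.0

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            morlet_tfr(np.zeros(100), 1000, np.array([8.0]))

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_tfr(np.zeros(2000), 100, np.array([60.0]))

    def test_stack_matches_single_trial_path(self, rng):
        trials = rng.normal(size=(3, 1500))
        freqs = np.arange(9.0, 16.0)
        power, fg, times, valid = tfr_stack(trials, 1000, freqs, onset_index=700)
        single = morlet_tfr(trials[1], 1000, freqs, onset_index=700)
        assert np.allclose(power[1], single.power)
        assert np.array_equal(valid, single.valid)
        assert np.array_equal(times, single.times_ms)

    def test_margin_mask_scales_with_wavelet_length(self):
        x = np.zeros(3000)
        tfr = morlet_tfr(x, 1000, np.array([8.0, 30.0]))
        # lower frequency -> longer wavelet -> wider invalid margin
        assert tfr.valid[0].sum() < tfr.valid[1].sum()


class TestVsIndependentImplementation:
    def test_against_mne_morlet_power(self):
        """Cross-check in-band power against MNE's Morlet implementation."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000) + tone(13, 1000, 2)
        freqs = np.arange(10.0, 20.0)
        ours = morlet_tfr(x, 1000, freqs, n_cycles=7.0)
        theirs = mne.time_frequency.tfr_array_morlet(
            x[None, None, :], 1000.0, freqs, n_cycles=7.0, output="power",
            verbose="error",
        )[0, 0]
        sel = ours.valid.all(axis=0)
        # normalization conventions differ by a constant gain per frequency
        ratio = ours.power[:, sel] / theirs[:, sel]
        per_freq_gain = ratio.mean(axis=1, keepdims=True)
        assert np.allclose(ratio / per_freq_gain, 1.0, atol=0.02)
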