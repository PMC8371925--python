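import numpy as np
import pytest
from scipy.stats import kstest

import stimtrack as st
from stimtrack.coherence import (
    bandpass_analytic,
    compute_coherence,
    make_filter_bank,
)
from stimtrack.synthetic import powerlaw_noise, resample_trace


class TestFilterBank:
    def test_default_centers(self, bank):
        want = 2.0 ** np.arange(-1.0, 4.01, 0.5)
        assert np.array_equal(bank.center_freqs_hz, want)
        assert bank.n_bands == 11
        assert bank.center_freqs_hz[0] == 0.5
        assert bank.center_freqs_hz[-1] == 16.0

    def test_band_edges(self, bank):
        assert bank.bands_hz[2] == (0.8, 1.25)  # the 1-Hz bin
        for f, (lo, hi) in zip(bank.center_freqs_hz, bank.bands_hz):
            assert lo == 0.8 * f and hi == 1.25 * f

    def test_adjacent_bins_overlap(self, bank):
        for (lo1, hi1), (lo2, hi2) in zip(bank.bands_hz, bank.bands_hz[1:]):
            assert hi1 > lo2  # 1.25 > 0.8 * sqrt(2)

    def test_inverted_edges_rejected(self):
        with pytest.raises(st.ParameterError):
            make_filter_bank(edge_factors=(1.25, 0.8))


class TestBandpassAnalytic:
    fs = 250.0

    def test_in_band_sinusoid_envelope_and_phase(self):
        t = np.arange(int(60 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 1.0 * t)
        band = bandpass_analytic(x, (0.8, 1.25), self.fs)
        core = slice(int(5 * self.fs), -int(5 * self.fs))
        env = band.power[core]
        assert env.std() / env.mean() < 0.05
        rate = np.diff(np.unwrap(band.phase[core])) * self.fs / (2 * np.pi)
        assert abs(rate.mean() - 1.0) < 0.01

    def test_out_of_band_attenuation(self):
        t = np.arange(int(60 * self.fs)) / self.fs
        in_band = bandpass_analytic(np.sin(2 * np.pi * 1.0 * t), (0.8, 1.25), self.fs)
        out_band = bandpass_analytic(np.sin(2 * np.pi * 4.0 * t), (0.8, 1.25), self.fs)
        core = slice(int(5 * self.fs), -int(5 * self.fs))
        ratio = out_band.power[core].mean() / in_band.power[core].mean()
        assert ratio < 10 ** (-20 / 20)  # >= 20 dB down, two octaves out

    def test_zero_phase_time_reversal_symmetry(self):
        """Filtering-then-reversing equals reversing-then-filtering
        (zero-phase symmetry).  The probe signal is tapered to zero at
        both ends so finite-length edge transients — which the global
        FFT Hilbert kernel would otherwise smear everywhere — vanish."""
        from scipy.signal.windows import tukey

        rng = np.random.default_rng(0)
        n = 20_000
        x = rng.standard_normal(n) * tukey(n, 0.2)
        fwd = bandpass_analytic(x, (2, 4), self.fs)
        rev = bandpass_analytic(x[::-1], (2, 4), self.fs)
        core = slice(n // 4, 3 * n // 4)
        assert np.allclose(fwd.power[core], rev.power[::-1][core], atol=1e-6)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(st.ParameterError):
            bandpass_analytic(np.ones(100), (100.0, 130.0), 250.0)


class TestComputeCoherence:
    def test_identical_signals_give_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        b = bandpass_analytic(x, (0.8, 1.25), 250.0)
        assert abs(compute_coherence(b, b) - 1.0) < 1e-12

    def test_constant_phase_lag_gives_one(self):
        t = np.arange(20_000) / 250.0
        a = bandpass_analytic(np.sin(2 * np.pi * t), (0.8, 1.25), 250.0)
        b = bandpass_analytic(np.sin(2 * np.pi * t + 1.234), (0.8, 1.25), 250.0)
        assert compute_coherence(a, b) > 0.99

    def test_random_phases_near_zero(self):
        rng = np.random.default_rng(2)
        n = 10_000
        theta = rng.uniform(-np.pi, np.pi, n)
        a = st.AnalyticBand(theta, np.ones(n), (0.8, 1.25), 250.0)
        b = st.AnalyticBand(np.zeros(n), np.ones(n), (0.8, 1.25), 250.0)
        # expected resultant length of n random unit phasors ~ sqrt(pi/4n)
        assert compute_coherence(a, b) < 0.05

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 8000))
        a = bandpass_analytic(x, (2, 4), 250.0)
        b = bandpass_analytic(y, (2, 4), 250.0)
        b_scaled = st.AnalyticBand(b.phase, 7.3 * b.power, b.band, b.rate_hz)
        assert np.isclose(
            compute_coherence(a, b), compute_coherence(a, b_scaled), rtol=1e-12
        )

    def test_weights_and_errors(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 1000))
        a = bandpass_analytic(x, (2, 4), 250.0)
        b = bandpass_analytic(y, (2, 4), 250.0)
        w = np.ones(1000)
        assert np.isclose(
            compute_coherence(a, b, w), compute_coherence(a, b), rtol=1e-12
        )
        with pytest.raises(st.DegenerateInputError):
            compute_coherence(a, b, np.zeros(1000))
        with pytest.raises(st.InputError):
            compute_coherence(a, b, np.ones(999))


class TestCoherenceMap:
    def test_coupled_channel_peaks_at_coupled_bin(self, layout):
        trace = st.generate_motion_trace(180, 30, seed=5)
        spec = st.CouplingSpec(["C3"], (0.8, 1.25), 2.0)
        eeg = st.generate_eeg(trace, layout, spec, eeg_rate_hz=125.0, seed=6)
        stim = st.MotionTrace(resample_trace(trace, 125.0), 125.0)
        cmap = st.coherence_map(eeg, stim)
        ch, bin_ = np.unravel_index(np.argmax(cmap.values), cmap.values.shape)
        assert cmap.channel_labels[ch] == "C3"
        assert cmap.bin_centers_hz[bin_] == 1.0
        assert np.all(cmap.values >= 0) and np.all(cmap.values <= 1)

    def test_length_mismatch_rejected(self, layout):
        trace = st.generate_motion_trace(10, 30, seed=0)
        eeg = st.generate_eeg(trace, layout, st.CouplingSpec(), eeg_rate_hz=125.0, seed=0)
        bad = st.MotionTrace(np.ones(100), rate_hz=125.0)
        with pytest.raises(st.InputError):
            st.coherence_map(eeg, bad)


class TestSurrogates:
    def _uncoupled(self, dur=120.0, fs=100.0, n_ch=8, seed=0):
        rng = np.random.default_rng(seed)
        trace = st.generate_motion_trace(dur, 30, seed=seed)
        stim = st.MotionTrace(resample_trace(trace, fs), fs)
        labels = [f"c{i}" for i in range(n_ch)]
        eeg = st.EEGRecording(
            powerlaw_noise(int(dur * fs), n_ch, 1.0, fs, rng), fs, labels,
            rng.standard_normal((n_ch, 3)),
        )
        return eeg, stim

    def test_reproducible_and_offsets_in_range(self):
        eeg, stim = self._uncoupled()
        a = st.surrogate_null(eeg, stim, n_shifts=10, seed=9)
        b = st.surrogate_null(eeg, stim, n_shifts=10, seed=9)
        assert np.array_equal(a.values, b.values)
        min_shift = int(10.0 * eeg.rate_hz)
        assert np.all(a.shift_offsets >= min_shift)
        assert np.all(a.shift_offsets <= eeg.n_samples - min_shift)

    def test_fast_path_matches_refiltering(self):
        eeg, stim = self._uncoupled(dur=60.0, n_ch=4)
        fast = st.surrogate_null(eeg, stim, n_shifts=8, seed=3)
        slow = st.surrogate_null(eeg, stim, n_shifts=8, seed=3, refilter=True)
        assert np.array_equal(fast.shift_offsets, slow.shift_offsets)
        assert np.median(np.abs(fast.values - slow.values)) < 5e-3

    def test_zero_offset_equals_empirical(self):
        """Identity rotation reproduces the empirical map exactly."""
        eeg, stim = self._uncoupled(dur=60.0, n_ch=4)
        emp, _ = st.empirical_and_null(eeg, stim, n_shifts=5, seed=0)
        direct = st.coherence_map(eeg, stim)
        assert np.allclose(emp.values, direct.values, atol=1e-9)

    def test_rotation_preserves_welch_spectrum(self):
        """Circular rotation only perturbs the Welch estimate through the
        segments straddling the wrap boundary (< 1% here)."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(60_000)
        spec = st.welch_psd(x, 64, 32, rate_hz=30.0)
        rolled = st.welch_psd(np.roll(x, 32 * 401), 64, 32, rate_hz=30.0)
        rel = np.abs(spec.power - rolled.power).sum() / spec.power.sum()
        assert rel < 0.01

    def test_mean_surrogate_matches_resultant_length_expectation(self):
        """For unrelated signals, mean surrogate coherence is near the
        random-phasor resultant-length level sqrt(pi / 4 n_eff)."""
        eeg, stim = self._uncoupled(dur=120.0, n_ch=4, seed=1)
        null = st.surrogate_null(eeg, stim, n_shifts=60, seed=2)
        # effective n is reduced by autocorrelation within a band; the
        # expectation only pins the order of magnitude
        mean_coh = null.values.mean()
        assert 0.001 < mean_coh < 0.5

    def test_min_shift_too_large_rejected(self):
        eeg, stim = self._uncoupled(dur=30.0, n_ch=2)
        with pytest.raises(st.ParameterError):
            st.surrogate_null(eeg, stim, n_shifts=5, min_shift_s=20.0, seed=0)


class TestZscoreMap:
    def test_definitional_values(self, bank):
        rng = np.random.default_rng(0)
        sur = rng.standard_normal((50, 3, bank.n_bands)) * 0.1 + 0.5
        null = st.SurrogateDistribution(sur, np.arange(50), bank.center_freqs_hz)
        mu = sur.mean(axis=0)
        sd = sur.std(axis=0, ddof=1)
        emp = st.CoherenceMap(mu, bank.center_freqs_hz, "raw")
        z0 = st.zscore_map(emp, null)
        assert np.allclose(z0.values, 0.0, atol=1e-12)
        emp2 = st.CoherenceMap(np.clip(mu + 2 * sd, 0, 1), bank.center_freqs_hz, "raw")
        z2 = st.zscore_map(emp2, null)
        assert np.allclose(z2.values, 2.0, atol=1e-9)

    def test_null_z_is_standard_normal(self, layout):
        """Uncoupled subject: pooled z-scores ~ N(0, 1) (KS p > 0.01)."""
        trace = st.generate_motion_trace(300, 30, seed=1)
        eeg = st.generate_eeg(trace, layout, st.CouplingSpec(), eeg_rate_hz=125.0, seed=101)
        stim = st.MotionTrace(resample_trace(trace, 125.0), 125.0)
        emp, null = st.empirical_and_null(eeg, stim, n_shifts=100, seed=201)
        z = st.zscore_map(emp, null).values.ravel()
        assert abs(z.mean()) < 0.15
        assert abs(z.std() - 1.0) < 0.2
        assert kstest(z, "norm").pvalue > 0.01

    def test_zero_sd_rejected(self, bank):
        sur = np.ones((10, 2, bank.n_bands)) * 0.3
        null = st.SurrogateDistribution(sur, np.arange(10), bank.center_freqs_hz)
        emp = st.CoherenceMap(np.full((2, bank.n_bands), 0.3), bank.center_freqs_hz, "raw")
        with pytest.raises(st.DegenerateInputError):
            st.zscore_map(emp, null)
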