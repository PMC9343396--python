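"""Averaging routes, comb selection, jitter correction and metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fwmot as fw
from fwmot.demux import project_sinusoids, synthesize, _gram
from conftest import peak_in_window


def _noise_record(samples, fs, rep_rate, n_pulses):
    """Wrap raw samples as a single-train record for the averaging routes."""
    scheme = fw.MultiplexScheme.fwm(rep_rate, 0.0, n_pulses, n_wavelengths=1)
    return fw.AcquisitionRecord(samples=np.asarray(samples, float),
                                sampling_rate=fs, scheme=scheme,
                                trigger_times=[np.arange(n_pulses) / rep_rate])


class TestProjectionMachinery:
    def test_gram_matches_explicit_inner_products(self):
        """Closed-form Dirichlet Gram equals the numerically built one."""
        rng = np.random.default_rng(0)
        fs, n = 1e6, 913
        freqs = np.sort(rng.uniform(1e3, 4.9e5, 7))
        t = np.arange(n) / fs
        cols = np.concatenate([np.cos(2 * np.pi * freqs[:, None] * t),
                               np.sin(2 * np.pi * freqs[:, None] * t)])
        explicit = cols @ cols.T
        np.testing.assert_allclose(_gram(freqs, n, fs), explicit,
                                   rtol=1e-9, atol=1e-7)

    def test_projection_recovers_known_coefficients(self):
        fs, n = 1e6, 4096
        freqs = np.array([12e3, 37.5e3, 121e3])
        t = np.arange(n) / fs
        truth = np.array([1.5 - 0.5j, -0.3 + 2.0j, 0.25 + 0.0j])
        x = sum(np.real(c * np.exp(2j * np.pi * f * t))
                for c, f in zip(truth, freqs))
        # diagonal projection carries Dirichlet-sidelobe leakage ...
        got = project_sinusoids(x, fs, freqs, method="independent")
        np.testing.assert_allclose(got, truth, atol=0.02)
        # ... the joint solve is exact to solver precision
        np.testing.assert_allclose(project_sinusoids(x, fs, freqs), truth,
                                   atol=1e-9)

    def test_synthesize_round_trip(self):
        fs = 1e6
        freqs = np.array([10e3, 30e3])
        coeffs = np.array([1.0 - 2.0j, 0.5 + 0.25j])
        t = np.arange(500) / fs
        direct = sum(np.real(c * np.exp(2j * np.pi * f * t))
                     for c, f in zip(coeffs, freqs))
        np.testing.assert_allclose(synthesize(freqs, coeffs, fs, 500), direct,
                                   atol=1e-12)


class TestTdAverage:
    def test_constant_record_is_unchanged(self):
        rec = _noise_record(np.full(1000, 3.3), 1e6, 1e4, 10)
        out = fw.td_average(rec, 1e4, 10)
        np.testing.assert_allclose(out.samples, 3.3)

    def test_periodic_record_returns_one_period_exactly(self):
        rng = np.random.default_rng(1)
        period = rng.normal(size=100)
        rec = _noise_record(np.tile(period, 8), 1e6, 1e4, 8)
        out = fw.td_average(rec, 1e4, 8)
        np.testing.assert_allclose(out.samples, period, atol=1e-14)

    def test_white_noise_std_shrinks_by_sqrt_np(self):
        """Monte-Carlo: 100-fold averaging divides the noise std by 10."""
        rng = np.random.default_rng(2)
        outs = []
        for _ in range(30):
            rec = _noise_record(rng.normal(size=100 * 100), 1e6, 1e4, 100)
            outs.append(fw.td_average(rec, 1e4, 100).samples)
        assert np.std(np.concatenate(outs)) == pytest.approx(0.1, rel=0.05)

    def test_too_short_record_raises(self):
        rec = _noise_record(np.zeros(500), 1e6, 1e4, 10)
        with pytest.raises(fw.InvalidParameterError):
            fw.td_average(rec, 1e4, 10)

    def test_non_integer_samples_per_period_resamples(self):
        """A pure comb harmonic survives averaging on an off-grid period."""
        fs, rep = 1e6, 9.7e3     # 103.09 samples per period
        n_p = 40
        t = np.arange(int(n_p / rep * fs)) / fs
        x = np.sin(2 * np.pi * 3 * rep * t)
        rec = _noise_record(x, fs, rep, n_p)
        out = fw.td_average(rec, rep, n_p)
        expect = np.sin(2 * np.pi * 3 * rep * out.times)
        assert np.max(np.abs(out.samples - expect)) < 0.02


class TestCombFilter:
    def test_comb_harmonic_passes_offcomb_suppressed(self):
        fs, rep, n_p = 1e6, 1e4, 50
        t = np.arange(n_p * 100) / fs
        k_in = np.sin(2 * np.pi * 3 * rep * t)
        k_half = np.sin(2 * np.pi * 3.5 * rep * t)
        rec_in = _noise_record(k_in, fs, rep, n_p)
        rec_half = _noise_record(k_half, fs, rep, n_p)
        harm = np.arange(1, 50)
        kept = fw.comb_filter(rec_in, rep, harm)
        rejected = fw.comb_filter(rec_half, rep, harm)
        assert np.max(np.abs(kept.samples - np.sin(2 * np.pi * 3 * rep * kept.times))) < 1e-9
        assert np.max(np.abs(rejected.samples)) < 0.01

    @given(seed=st.integers(0, 50))
    def test_all_harmonics_equal_td_average_minus_dc(self, seed):
        """Full-comb selection is Fourier-equivalent to period averaging.

        On an integer-period record with every harmonic up to Nyquist
        retained, the comb output equals the time-domain average with its
        DC removed, to numerical precision.
        """
        rng = np.random.default_rng(seed)
        fs, rep, n_p = 1e6, 1e4, 7    # 100 samples per period, even
        x = rng.normal(size=n_p * 100)
        rec = _noise_record(x, fs, rep, n_p)
        ta = fw.td_average(rec, rep, n_p)
        cf = fw.comb_filter(rec, rep, np.arange(1, 51))  # k = 50 is Nyquist
        dev = np.max(np.abs(ta.samples - ta.samples.mean() - cf.samples))
        assert dev < 1e-9 * np.ptp(ta.samples)

    def test_harmonic_above_nyquist_raises(self):
        rec = _noise_record(np.zeros(1000), 1e6, 1e4, 10)
        with pytest.raises(fw.InvalidParameterError):
            fw.comb_filter(rec, 1e4, [51])
        with pytest.raises(fw.InvalidParameterError):
            fw.comb_filter(rec, 1e4, [])

    def test_sqrt_np_snr_scaling_on_white_noise(self):
        """log-log slope of the noise-reduction factor vs N_p is 1/2."""
        rng = np.random.default_rng(3)
        fs, rep = 1e6, 1e4   # 100 samples per period
        n_ps = [4, 16, 64]
        gains = []
        for n_p in n_ps:
            stds = []
            for _ in range(25):
                x = rng.normal(size=n_p * 100)
                out = fw.comb_filter(_noise_record(x, fs, rep, n_p), rep,
                                     np.arange(1, 51))
                stds.append(np.std(out.samples))
            gains.append(1.0 / np.mean(stds))
        slope = np.polyfit(np.log10(n_ps), np.log10(gains), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)


@pytest.fixture(scope="module")
def two_laser_case(small_transducer):
    """Two lasers, disjoint absorbers, admissible offset, low noise."""
    fs = 20e6
    scheme = fw.MultiplexScheme.fwm(100e3, 500.0, 100,
                                    pulse_energies=100e-9, n_wavelengths=2)
    phantom = [
        fw.Absorber(depth=2e-3, per_wavelength_amplitude=(1e5, 0.0)),
        fw.Absorber(depth=5e-3, per_wavelength_amplitude=(0.0, 1e5)),
    ]
    noise = fw.NoiseModel(white_noise_std=2e-4, seed=21)
    rec = fw.simulate_record(scheme, phantom, small_transducer, noise,
                             sampling_rate=fs)
    windows = {1: (1.2e-6, 1.5e-6), 2: (3.2e-6, 3.5e-6)}
    return rec, scheme, windows


class TestDemuxAll:
    def test_each_wavelength_sees_only_its_absorber(self, two_laser_case,
                                                    small_band):
        rec, scheme, windows = two_laser_case
        ascans = fw.demux_all(rec, band=small_band)
        assert [a.wavelength_id for a in ascans] == [1, 2]
        for a, own in zip(ascans, (1, 2)):
            other = 2 if own == 1 else 1
            own_peak = peak_in_window(a, windows[own])
            other_peak = peak_in_window(a, windows[other])
            noise_floor = np.std(a.samples[int(8e-6 * a.sampling_rate):])
            assert own_peak > 3 * noise_floor
            assert other_peak < own_peak / 10

    def test_zero_record_gives_zero_ascans(self, small_band):
        scheme = fw.MultiplexScheme.fwm(100e3, 500.0, 50, n_wavelengths=2)
        rec = fw.AcquisitionRecord(
            samples=np.zeros(20000), sampling_rate=20e6, scheme=scheme,
            trigger_times=[t.start_offset + np.arange(t.n_pulses) / t.rep_rate
                           for t in scheme.trains])
        for a in fw.demux_all(rec, band=small_band):
            np.testing.assert_allclose(a.samples, 0.0, atol=1e-12)

    def test_linearity(self, two_laser_case, small_band):
        rec, scheme, _ = two_laser_case
        rec2 = fw.AcquisitionRecord(samples=2.5 * rec.samples,
                                    sampling_rate=rec.sampling_rate,
                                    scheme=scheme,
                                    trigger_times=rec.trigger_times)
        a1 = fw.demux_all(rec, band=small_band)
        a2 = fw.demux_all(rec2, band=small_band)
        for x, y in zip(a1, a2):
            np.testing.assert_allclose(y.samples, 2.5 * x.samples, atol=1e-9)

    def test_invariant_to_off_comb_interferer(self, two_laser_case, small_band):
        """An interferer at (k+1/2)*f_rep,1 leaves the A-scans unchanged."""
        rec, scheme, _ = two_laser_case
        t = rec.times
        interferer = 3e-3 * np.sin(2 * np.pi * 20.5 * 100e3 * t)
        rec2 = fw.AcquisitionRecord(samples=rec.samples + interferer,
                                    sampling_rate=rec.sampling_rate,
                                    scheme=scheme,
                                    trigger_times=rec.trigger_times)
        for a, b in zip(fw.demux_all(rec, band=small_band),
                        fw.demux_all(rec2, band=small_band)):
            ref = np.max(np.abs(a.samples))
            assert np.max(np.abs(a.samples - b.samples)) < 0.01 * ref

    def test_infeasible_offset_warns(self, small_transducer, small_band):
        scheme = fw.MultiplexScheme.fwm(100e3, 1.0, 50, n_wavelengths=2)
        rec = fw.simulate_record(scheme, [], small_transducer,
                                 fw.NoiseModel(white_noise_std=1e-4, seed=2),
                                 sampling_rate=20e6)
        with pytest.warns(UserWarning, match="admissible"):
            fw.demux_all(rec, band=small_band)


class TestPulseVariationCorrection:
    def _jitter_case(self, small_transducer, cv, jitter):
        fs = 20e6
        scheme = fw.MultiplexScheme.fwm(100e3, 0.0, 40, pulse_energies=100e-9,
                                        n_wavelengths=1)
        ph = [fw.Absorber(depth=3e-3, per_wavelength_amplitude=(1e5,))]
        noise = fw.NoiseModel(white_noise_std=2e-4, energy_jitter_cv=cv,
                              timing_jitter_std=jitter, seed=31)
        rec = fw.simulate_record(scheme, ph, small_transducer, noise,
                                 sampling_rate=fs)
        return rec, scheme

    def test_zero_reference_is_identity(self, small_transducer):
        rec, scheme = self._jitter_case(small_transducer, 0.0, 0.0)
        out = fw.correct_pulse_variations(rec, np.ones(40), np.zeros(40))
        np.testing.assert_allclose(out.samples, rec.samples, atol=1e-15)

    def test_known_shifts_realign_within_one_sample(self, small_transducer):
        """Per-period timing offsets are undone to within one sample.

        Jitter of +-2 samples visibly moves the wavelet peak inside each
        period; after correction every period's peak is back at the clean
        position to within one sample.
        """
        clean, _ = self._jitter_case(small_transducer, 0.0, 0.0)
        rec, _ = self._jitter_case(small_transducer, 0.0, 100e-9)
        fs = rec.sampling_rate
        per = 200    # samples per period
        out = fw.correct_pulse_variations(
            rec, np.ones(40), rec.pulse_timing_offsets[0])

        def peaks(samples):
            return np.array([np.argmax(np.abs(samples[k * per:(k + 1) * per]))
                             for k in range(40)])
        p_clean, p_jit, p_corr = (peaks(x.samples) for x in (clean, rec, out))
        assert np.max(np.abs(p_jit - p_clean)) >= 2      # jitter is visible
        assert np.max(np.abs(p_corr - p_clean)) <= 1     # and undone

    def test_correction_restores_snr_within_1db(self, small_transducer):
        """5% energy CV and 2 ns timing jitter corrected to the clean SNR."""
        windows = dict(signal_window=(1.8e-6, 2.2e-6), noise_window=(5e-6, 9e-6))
        clean_rec, _ = self._jitter_case(small_transducer, 0.0, 0.0)
        snr_clean = fw.measure_snr(fw.td_average(clean_rec, 100e3, 40),
                                   **windows).snr_db
        rec, _ = self._jitter_case(small_transducer, 0.05, 2e-9)
        corrected = fw.correct_pulse_variations(
            rec, rec.pulse_energy_factors[0], rec.pulse_timing_offsets[0])
        snr_corr = fw.measure_snr(fw.td_average(corrected, 100e3, 40),
                                  **windows).snr_db
        assert abs(snr_corr - snr_clean) < 1.0

    def test_mismatched_reference_raises(self, small_transducer):
        rec, _ = self._jitter_case(small_transducer, 0.0, 0.0)
        with pytest.raises(fw.InvalidParameterError):
            fw.correct_pulse_variations(rec, np.ones(39), np.zeros(39))


class TestMetrics:
    def _ascan(self, samples, fs=20e6):
        return fw.AveragedAScan(samples=np.asarray(samples, float),
                                sampling_rate=fs, period=len(samples) / fs)

    def test_known_amplitude_and_noise(self):
        rng = np.random.default_rng(8)
        fs = 20e6
        x = rng.normal(0, 1e-4, 200)
        x[40:44] = [5e-3, -5e-3, 3e-3, -1e-3]
        rep = fw.measure_snr(self._ascan(x, fs), (1.9e-6, 2.3e-6), (5e-6, 9e-6))
        assert rep.snr_db == pytest.approx(10 * np.log10(5e-3 / 1e-4), abs=0.5)
        assert rep.has_signal

    def test_reported_example_windows(self):
        """Constructed 12 mV peak over 90.6 uV floor reads 21.2 dB."""
        rng = np.random.default_rng(9)
        fs = 20e6
        x = rng.normal(0, 90.6e-6, 400)
        x[50] = 12e-3
        rep = fw.measure_snr(self._ascan(x, fs), (2.4e-6, 2.6e-6), (10e-6, 19e-6))
        assert rep.snr_db == pytest.approx(21.2, abs=0.2)

    def test_pure_noise_flagged_no_signal(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1e-4, 400)
        rep = fw.measure_snr(self._ascan(x), (0.0, 5e-6), (10e-6, 19e-6))
        assert not rep.has_signal

    def test_overlapping_windows_raise(self):
        with pytest.raises(fw.InvalidParameterError):
            fw.measure_snr(self._ascan(np.ones(400)), (0.0, 10e-6), (5e-6, 15e-6))

    def test_crosstalk_identical_ascans_are_zero_db(self):
        a = self._ascan(np.sin(np.arange(400)))
        b = self._ascan(np.sin(np.arange(400)))
        b.wavelength_id = 2
        m = fw.crosstalk_db([a, b], {1: (1e-6, 3e-6), 2: (1e-6, 3e-6)})
        np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_crosstalk_disjoint_wavelets(self):
        x = np.zeros(400); x[40] = 1.0; x[200] = 0.01
        y = np.zeros(400); y[200] = 1.0; y[40] = 0.001
        a, b = self._ascan(x), self._ascan(y)
        b.wavelength_id = 2
        m = fw.crosstalk_db([a, b], {1: (1.8e-6, 2.2e-6), 2: (9.8e-6, 10.2e-6)})
        assert m[0, 1] == pytest.approx(-20.0, abs=0.01)
        assert m[1, 0] == pytest.approx(-30.0, abs=0.01)
        assert m[0, 0] == m[1, 1] == 0.0
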