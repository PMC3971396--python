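"""Band-pass filtering, analytic signal, and mean-coupling-phase extraction."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from pacpredict.coupling import (
    CouplingPhaseMap,
    analytic_signal,
    band_pair,
    bandpass_filter,
    coupling_phase_map,
    mean_coupling_phase,
    phase_amplitude_histogram,
)
from pacpredict.synthetic import SyntheticSpec, generate_patient


def circ_diff(a, b):
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


class TestBandpassFilter:
    def test_zero_in_zero_out(self):
        out = bandpass_filter(np.zeros(2560), (8.0, 16.0), 256.0)
        assert np.allclose(out, 0.0)

    def test_steady_state_gain_at_band_center(self):
        fs, band = 256.0, (8.0, 16.0)
        f0 = np.sqrt(band[0] * band[1])  # geometric center
        t = np.arange(int(60 * fs)) / fs
        out = bandpass_filter(np.sin(2 * np.pi * f0 * t), band, fs)
        # oracle: squared-magnitude Butterworth response at f0
        sos = sp_signal.butter(8, band, btype="bandpass", fs=fs, output="sos")
        _, h = sp_signal.sosfreqz(sos, worN=[2 * np.pi * f0 / fs])
        expected = np.abs(h[0]) ** 2
        central = out[int(5 * fs) : int(55 * fs)]
        amp = np.abs(sp_signal.hilbert(central))[256:-256].mean()
        assert abs(amp - expected) < 0.01 * expected

    def test_zero_phase_alignment(self):
        fs, band = 256.0, (8.0, 16.0)
        f0 = np.sqrt(band[0] * band[1])
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = bandpass_filter(x, band, fs)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[2000:-2000], np.roll(y, k)[2000:-2000]) for k in lags]
        assert lags[np.argmax(xc)] == 0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(256), (40.0, 130.0), 256.0)

    def test_nonfinite_input_rejected(self):
        x = np.zeros(256)
        x[3] = np.inf
        with pytest.raises(ValueError):
            bandpass_filter(x, (8.0, 16.0), 256.0)


class TestAnalyticSignal:
    def test_pure_cosine_phase_and_amplitude(self):
        fs, f0 = 256.0, 5.0
        t = np.arange(int(10 * fs)) / fs
        phase, amp = analytic_signal(np.cos(2 * np.pi * f0 * t))
        interior = slice(256, -256)
        assert np.abs(amp[interior] - 1.0).max() < 0.01
        dphi = np.angle(np.exp(1j * np.diff(phase[interior])))
        assert np.allclose(dphi, 2 * np.pi * f0 / fs, atol=1e-3)

    def test_sin_lags_cos_by_quarter_cycle(self):
        fs, f0 = 256.0, 5.0
        t = np.arange(int(10 * fs)) / fs
        ph_cos, _ = analytic_signal(np.cos(2 * np.pi * f0 * t))
        ph_sin, _ = analytic_signal(np.sin(2 * np.pi * f0 * t))
        interior = slice(256, -256)
        d = circ_diff(ph_sin[interior], ph_cos[interior])
        assert np.allclose(d, -np.pi / 2, atol=0.02)

    def test_zero_input_flagged(self):
        phase, amp = analytic_signal(np.zeros(512))
        assert np.all(amp == 0.0)
        assert np.all(np.isnan(phase))


class TestPhaseAmplitudeHistogram:
    def test_constant_amplitude_uniform_phase(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 40000)
        hist = phase_amplitude_histogram(phase, np.ones_like(phase))
        assert hist.counts.sum() == phase.size
        assert np.allclose(hist.mean_amplitude, 1.0)

    def test_cosine_modulation_matches_bin_average(self):
        # analytic oracle: average of 1 + cos(phi) over each bin
        phase = np.linspace(-np.pi, np.pi, 400001, endpoint=False)
        amp = 1.0 + np.cos(phase)
        hist = phase_amplitude_histogram(phase, amp)
        lo, hi = hist.bin_edges[:-1], hist.bin_edges[1:]
        expected = 1.0 + (np.sin(hi) - np.sin(lo)) / (hi - lo)
        assert np.abs(hist.mean_amplitude - expected).max() < 1e-4

    def test_empty_bin_flagged(self):
        edges = np.linspace(-np.pi, np.pi, 41)
        keep = np.r_[np.linspace(-3.0, edges[7] - 0.01, 500),
                     np.linspace(edges[8] + 0.01, 3.0, 500)]
        hist = phase_amplitude_histogram(keep, np.ones_like(keep))
        assert hist.counts[7] == 0
        assert hist.empty[7]
        assert np.isnan(hist.mean_amplitude[7])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phase_amplitude_histogram(np.zeros(10), np.zeros(11))

    def test_count_conservation_random(self, rng):
        for _ in range(20):
            n = rng.integers(100, 5000)
            phase = rng.uniform(-np.pi, np.pi, n)
            hist = phase_amplitude_histogram(phase, rng.random(n))
            assert hist.counts.sum() == n


class TestMeanCouplingPhase:
    def test_single_occupied_bin(self):
        phase = np.full(100, -2.62)
        hist = phase_amplitude_histogram(phase, np.ones(100))
        phi, conc = mean_coupling_phase(hist)
        occupied = int(np.nonzero(hist.counts)[0][0])
        assert phi == pytest.approx(hist.bin_centers[occupied])
        assert conc == pytest.approx(1.0)

    def test_cosine_weighted_mean_matches_oracle(self):
        phase = np.linspace(-np.pi, np.pi, 200001, endpoint=False)
        amp = 1.0 + 0.5 * np.cos(phase - 1.0)
        hist = phase_amplitude_histogram(phase, amp)
        phi, conc = mean_coupling_phase(hist)
        # oracle: weighted circular mean over the 40 bins
        z = np.sum(hist.mean_amplitude * np.exp(1j * hist.bin_centers))
        assert abs(circ_diff(phi, np.angle(z))) < 1e-9
        assert abs(circ_diff(phi, 1.0)) < np.pi / 40
        assert conc > 0.1

    def test_flat_distribution_unreliable(self):
        phase = np.linspace(-np.pi, np.pi, 40000, endpoint=False)
        hist = phase_amplitude_histogram(phase, np.ones_like(phase))
        _, conc = mean_coupling_phase(hist)
        assert conc < 1e-6

    def test_all_empty_rejected(self):
        hist = phase_amplitude_histogram(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            mean_coupling_phase(hist)

    def test_raw_pair_oracle_equivalence(self, rng):
        """Binned estimate tracks the brute-force raw-sample circular mean."""
        for _ in range(10):
            target = rng.uniform(-np.pi, np.pi)
            phase = rng.uniform(-np.pi, np.pi, 30000)
            amp = 1.0 + 0.7 * np.cos(phase - target) + 0.1 * rng.normal(
                size=phase.size
            )
            amp = np.clip(amp, 0, None)
            hist = phase_amplitude_histogram(phase, amp)
            phi, _ = mean_coupling_phase(hist)
            brute = np.angle(np.sum(amp * np.exp(1j * phase)))
            assert abs(circ_diff(phi, brute)) < np.pi / 40

    def test_phase_offset_equivariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20000)
        amp = np.clip(1.0 + 0.6 * np.cos(phase - 0.5), 0, None)
        phi0, conc0 = mean_coupling_phase(
            phase_amplitude_histogram(phase, amp)
        )
        theta = 0.9
        shifted = np.angle(np.exp(1j * (phase + theta)))
        phi1, conc1 = mean_coupling_phase(
            phase_amplitude_histogram(shifted, amp)
        )
        assert abs(circ_diff(phi1, phi0 + theta)) < np.pi / 40
        assert conc1 == pytest.approx(conc0, abs=0.02)


class TestCouplingPhaseMap:
    def test_recovers_planted_phases(self, three_channel_recording,
                                     delta_lg_pair):
        rec, manifest = three_channel_recording
        cmap = coupling_phase_map(rec, delta_lg_pair)
        targets = manifest["interictal_phase_per_channel"]
        for ch, target in enumerate(targets):
            err = np.abs(circ_diff(cmap.phi_c[ch], target))
            assert err.max() < 0.15

    def test_concentration_monotone_in_depth(self):
        concs = []
        for depth in (0.0, 0.4, 0.8):
            spec = SyntheticSpec(
                n_channels=2, duration_s=240.0, seizure_onsets=(),
                modulation_depth=depth, seed=5,
            )
            rec, _ = generate_patient(spec)
            cmap = coupling_phase_map(rec, band_pair("delta", "LG", rec.fs))
            concs.append(cmap.concentration.mean(axis=1))
        assert np.all(concs[0] < concs[1])
        assert np.all(concs[1] < concs[2])

    def test_window_count_truncates(self):
        spec = SyntheticSpec(
            n_channels=1, duration_s=659.0, seizure_onsets=(), seed=2
        )
        rec, _ = generate_patient(spec)
        cmap = coupling_phase_map(rec, band_pair("delta", "LG", rec.fs))
        assert cmap.n_windows == 10

    def test_fft_path_agrees_with_filtfilt_hilbert(
        self, three_channel_recording, delta_lg_pair
    ):
        """Whole-record FFT extraction == literal filter + Hilbert route."""
        rec, _ = three_channel_recording
        x = rec.signals[0].astype(np.float64)
        filt = bandpass_filter(x, delta_lg_pair.low_hz, rec.fs)
        ph_ref, _ = analytic_signal(filt)
        cmap = coupling_phase_map(rec, delta_lg_pair)

        from pacpredict.coupling import (
            _band_analytic_fft,
            _zero_phase_gains,
        )
        import scipy.fft as sp_fft

        n = x.size
        pad = min(n - 1, int(60 * rec.fs))
        nfft = sp_fft.next_fast_len(n + 2 * pad)
        gains = _zero_phase_gains([delta_lg_pair.low_hz], rec.fs, nfft)
        z = _band_analytic_fft(x, gains, rec.fs, pad, nfft)[0]
        # the slow band rings for tens of seconds, so both routes only
        # agree away from their (differently handled) record edges; the
        # complex signals are compared because the phase alone is
        # ill-conditioned wherever the envelope passes near zero
        filt_z = filt + 1j * np.imag(sp_signal.hilbert(filt))
        interior = slice(int(45 * rec.fs), -int(45 * rec.fs))
        rms = np.sqrt(np.mean(np.abs(filt_z[interior]) ** 2))
        err = np.abs(z[interior] - filt_z[interior]) / rms
        assert err.max() < 0.02
        # and the phase agrees wherever the envelope is healthy
        healthy = np.abs(filt_z[interior]) > 0.5 * rms
        d = circ_diff(np.angle(z[interior][healthy]),
                      ph_ref[interior][healthy])
        assert np.abs(d).max() < 0.05
        assert cmap.n_windows == 5

    def test_hg_band_narrows_at_low_rate(self):
        assert band_pair("theta", "HG", 256.0).high_hz == (70.0, 120.0)
        assert band_pair("theta", "HG", 1024.0).high_hz == (70.0, 140.0)

    def test_serialization_roundtrip(self, phase_map_factory):
        cmap = phase_map_factory(np.array([[0.1, 0.2], [1.0, np.nan]]))
        df = cmap.to_frame()
        assert len(df) == 4
        assert df["phi_c"].isna().sum() == 1
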