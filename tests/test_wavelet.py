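"""Morlet CWT: grids, eigenfunction behaviour, phase/amplitude extraction."""

import numpy as np
import pytest

from kindleictal.errors import AliasingError, InvalidArgumentError
from kindleictal.signal_io import Trace
from kindleictal.wavelet import (
    FrequencyGrid,
    MorletParams,
    WaveletSpectrum,
    cwt_morlet,
    extract_amplitude,
    extract_phase,
    make_log_grid,
)


class TestLogGrid:
    @pytest.mark.parametrize(
        "fmin,fmax,ppo,n_expected",
        [(0.25, 512.0, 4, 45), (32.0, 512.0, 1, 5), (1.0, 30.0, 4, 21)],
    )
    def test_sizes(self, fmin, fmax, ppo, n_expected):
        g = make_log_grid(fmin, fmax, ppo)
        assert len(g) == n_expected
        assert g.frequencies[0] == pytest.approx(fmin, rel=1e-12)
        assert g.frequencies[-1] == pytest.approx(fmax, rel=1e-9)

    def test_octave_grid_values(self):
        g = make_log_grid(32.0, 512.0, 1)
        np.testing.assert_allclose(g.frequencies, [32, 64, 128, 256, 512], rtol=1e-12)

    def test_constant_ratio(self):
        g = make_log_grid(1.0, 30.0, 4)
        ratios = g.frequencies[1:] / g.frequencies[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_invalid_bounds(self):
        with pytest.raises(InvalidArgumentError):
            make_log_grid(10.0, 1.0, 4)


class TestCwt:
    def test_sinusoid_is_eigenfunction(self, tone_trace):
        tr = tone_trace(8.0, fs=500.0, duration=10.0)
        grid = make_log_grid(2.0, 32.0, 4)
        spec = cwt_morlet(tr, grid)
        amp = extract_amplitude(spec)
        k8 = grid.nearest_index(8.0)
        # the 8 Hz row dominates
        assert np.argmax(amp[tr.n // 2, :]) == k8
        # constant modulus away from the edges
        inner = amp[~spec.coi_mask()[:, k8], k8]
        assert inner.std() / inner.mean() < 0.05

    def test_zero_trace_gives_zero_coefficients(self):
        spec = cwt_morlet(Trace(np.zeros(1000), fs=500.0), make_log_grid(2, 64, 2))
        assert np.all(spec.coefficients == 0)

    def test_superposition_ridge_ratio(self, tone_trace):
        grid = make_log_grid(2.0, 128.0, 4)
        fs, dur = 1000.0, 10.0
        both = cwt_morlet(tone_trace([4.0, 64.0], fs=fs, duration=dur, amps=[1.0, 0.5]), grid)
        lone4 = cwt_morlet(tone_trace(4.0, fs=fs, duration=dur), grid)
        lone64 = cwt_morlet(tone_trace(64.0, fs=fs, duration=dur, amps=[0.5]), grid)
        mid = int(dur * fs / 2)
        k4, k64 = grid.nearest_index(4.0), grid.nearest_index(64.0)
        a = np.abs(both.coefficients[mid])
        ratio_both = a[k4] / a[k64]
        ratio_single = np.abs(lone4.coefficients[mid, k4]) / np.abs(
            lone64.coefficients[mid, k64]
        )
        assert ratio_both == pytest.approx(ratio_single, rel=0.05)

    def test_linearity_and_time_shift(self, tone_trace):
        tr = tone_trace(10.0, fs=500.0, duration=6.0)
        grid = make_log_grid(4.0, 32.0, 4)
        c1 = cwt_morlet(tr, grid).coefficients
        c3 = cwt_morlet(Trace(3.0 * tr.samples, tr.fs), grid).coefficients
        np.testing.assert_allclose(c3, 3.0 * c1, rtol=1e-9, atol=1e-12 * np.abs(c1).max())
        shift = 250
        shifted = Trace(np.roll(tr.samples, shift), tr.fs)
        cs = cwt_morlet(shifted, grid).coefficients
        np.testing.assert_allclose(
            np.abs(cs[1000 + shift, :]),
            np.abs(c1[1000, :]),
            rtol=0.02,
            atol=1e-6 * np.abs(c1[1000, :]).max(),
        )

    def test_grid_above_nyquist_raises(self):
        with pytest.raises(AliasingError):
            cwt_morlet(Trace(np.zeros(1000), fs=100.0), make_log_grid(2.0, 64.0, 2))


class TestPhaseAmplitude:
    def test_extraction_from_known_coefficients(self):
        coeffs = np.array([[1 + 0j, 0 + 1j, 3 + 4j, -1 + 0j]])
        spec = WaveletSpectrum(
            coeffs, FrequencyGrid(np.array([1.0, 2.0, 4.0, 8.0]), 1, 8, 1), 100.0,
            MorletParams(),
        )
        phase = extract_phase(spec)
        amp = extract_amplitude(spec)
        assert phase[0, 0] == pytest.approx(0.0, abs=1e-15)
        assert phase[0, 1] == pytest.approx(np.pi / 2, abs=1e-15)
        assert phase[0, 3] == pytest.approx(np.pi, abs=1e-15)  # (-pi, pi]
        assert amp[0, 2] == pytest.approx(5.0, abs=1e-12)
        assert extract_amplitude(spec)[0, 0] == pytest.approx(1.0)

    def test_phase_advances_at_tone_frequency(self, tone_trace):
        tr = tone_trace(8.0, fs=500.0, duration=10.0)
        grid = make_log_grid(4.0, 16.0, 4)
        spec = cwt_morlet(tr, grid)
        k8 = grid.nearest_index(8.0)
        inner = slice(1000, tr.n - 1000)
        ph = np.unwrap(extract_phase(spec)[inner, k8])
        t = tr.times()[inner]
        slope = np.polyfit(t, ph, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 8.0, rel=0.01)

    def test_am_envelope_recovered(self):
        # depth-1 modulation of an 80 Hz carrier by 8 Hz: the amplitude row
        # at 80 Hz oscillates at the modulation frequency
        fs, dur = 1000.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        env = (1 + np.cos(2 * np.pi * 8.0 * t)) / 2
        tr = Trace(env * np.cos(2 * np.pi * 80.0 * t), fs)
        grid = make_log_grid(40.0, 160.0, 4)
        amp = extract_amplitude(cwt_morlet(tr, grid))[:, grid.nearest_index(80.0)]
        inner = amp[2000:-2000] - amp[2000:-2000].mean()
        spectrum = np.abs(np.fft.rfft(inner))
        freqs = np.fft.rfftfreq(inner.size, 1 / fs)
        assert freqs[np.argmax(spectrum)] == pytest.approx(8.0, abs=0.2)


def test_matches_pywt_reference_on_tone(tone_trace):
    """Independent cross-check of the transform against pywavelets' cmor."""
    pywt = pytest.importorskip("pywt")
    fs = 500.0
    tr = tone_trace(8.0, fs=fs, duration=8.0)
    params = MorletParams()
    grid = make_log_grid(2.0, 32.0, 4)
    ours = np.abs(cwt_morlet(tr, grid, params).coefficients)
    scales = params.center_frequency * fs / grid.frequencies
    ref, _ = pywt.cwt(
        tr.samples,
        scales,
        f"cmor{params.bandwidth}-{params.center_frequency}",
        sampling_period=1 / fs,
        method="fft",
    )
    ref = np.abs(ref).T  # pywt returns (scales, time)
    mid = ours.shape[0] // 2
    ours_profile = ours[mid] / ours[mid].max()
    ref_profile = ref[mid] / ref[mid].max()
    # same normalized frequency profile and same peak row
    assert np.argmax(ours_profile) == np.argmax(ref_profile)
    np.testing.assert_allclose(ours_profile, ref_profile, atol=0.05)
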