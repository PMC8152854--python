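"""KL modulation index, PAC windowing/averaging, wavelet phase coherence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kindleictal.coupling import (
    Comodulogram,
    PACWindowSeries,
    artifact_mask,
    make_log_grid,
    mean_pac,
    modulation_index,
    pac_windows,
    wpc,
    wpc_null_bias,
)
from kindleictal.errors import AlignmentError, InvalidArgumentError
from kindleictal.events import DischargeEvent, segment_epochs
from kindleictal.signal_io import Trace
from kindleictal.synthdata import SynthConfig, generate_background, inject_artifact
from kindleictal.wavelet import FrequencyGrid


def kl_mi_oracle(phase, amplitude, n_bins=18):
    """Brute-force per-sample KL modulation index (independent oracle)."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = np.zeros(n_bins)
    for k in range(n_bins):
        sel = [
            i
            for i in range(len(phase))
            if edges[k] < phase[i] <= edges[k + 1]
            or (k == 0 and phase[i] <= edges[0])
        ]
        if sel:
            means[k] = sum(amplitude[i] for i in sel) / len(sel)
    p = means / means.sum()
    kl = 0.0
    for pk in p:
        if pk > 0:
            kl += pk * np.log(pk * n_bins)
    return kl / np.log(n_bins)


class TestModulationIndex:
    def test_uniform_amplitude_gives_zero(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(-np.pi, np.pi, 20000)
        assert modulation_index(ph, np.ones(20000)) == pytest.approx(0.0, abs=1e-10)

    def test_single_bin_concentration_gives_one(self):
        ph = np.linspace(-np.pi + 1e-6, np.pi, 18000)
        amp = np.where((ph > 0) & (ph <= np.pi / 9), 1.0, 0.0)
        assert modulation_index(ph, amp) == pytest.approx(1.0, abs=1e-10)

    def test_two_level_distribution_matches_oracle(self):
        # half the amplitude mass in one 20-degree bin, the rest spread
        # evenly: MI = 0.5*ln(81/17)/ln 18
        n_bins = 18
        centers = -np.pi + (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
        ph = np.repeat(centers, 10)
        amp = np.where(np.isclose(ph, centers[4]), 8.5, 0.5)  # 85 vs 5*17
        mi = modulation_index(ph, amp, n_bins)
        expected = 0.5 * np.log(81 / 17) / np.log(18)
        assert mi == pytest.approx(expected, abs=1e-12)
        assert mi == pytest.approx(kl_mi_oracle(list(ph), list(amp)), abs=1e-12)

    def test_vectorized_equals_naive_loop(self):
        rng = np.random.default_rng(1)
        ph = rng.uniform(-np.pi, np.pi, 10000)
        amp = rng.gamma(2.0, 1.0, 10000) * (1 + 0.5 * np.cos(ph))
        assert modulation_index(ph, amp) == pytest.approx(
            kl_mi_oracle(list(ph), list(amp)), abs=1e-12
        )

    def test_invariant_to_amplitude_rescaling(self):
        rng = np.random.default_rng(2)
        ph = rng.uniform(-np.pi, np.pi, 5000)
        amp = 1 + 0.3 * np.cos(ph) + 0.1 * rng.random(5000)
        assert modulation_index(ph, amp) == pytest.approx(
            modulation_index(ph, 137.0 * amp), abs=1e-14
        )

    def test_invariant_to_bin_rotation(self):
        rng = np.random.default_rng(3)
        ph = (rng.integers(0, 18, 5000) + 0.5) * (2 * np.pi / 18) - np.pi
        amp = rng.gamma(2.0, 1.0, 5000)
        mi0 = modulation_index(ph, amp)
        rotated = np.angle(np.exp(1j * (ph + 3 * 2 * np.pi / 18)))
        assert modulation_index(rotated, amp) == pytest.approx(mi0, abs=1e-12)

    def test_all_zero_amplitude_warns_nan(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = modulation_index(np.linspace(-3, 3, 100), np.zeros(100))
        assert np.isnan(out)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        ph = rng.uniform(-np.pi, np.pi, 500)
        amp = rng.gamma(1.5, 1.0, 500)
        assert 0.0 <= modulation_index(ph, amp) <= 1.0


class TestPacWindows:
    def test_min_cycles_reliability_flags(self):
        trace = generate_background(SynthConfig(12.0, 256.0, seed=4))
        grid_phase = FrequencyGrid(np.array([0.5, 1.0, 2.0]), 0.5, 2.0, 1)
        grid_amp = FrequencyGrid(np.array([32.0, 64.0]), 32, 64, 1)
        series = pac_windows(trace, grid_phase, grid_amp, window_s=4.0)
        # 1 Hz sees exactly 4 cycles in a 4-s window: computed, not flagged
        np.testing.assert_array_equal(series.reliable_phase_rows, [False, True, True])

    def test_artifact_window_masked_end_to_end(self):
        trace = generate_background(SynthConfig(24.0, 256.0, seed=5))
        trace, _ = inject_artifact(trace, [13.0], magnitude=12.0, width=0.2)
        grid_phase = FrequencyGrid(np.array([4.0]), 4, 4, 1)
        grid_amp = FrequencyGrid(np.array([32.0]), 32, 32, 1)
        series = pac_windows(trace, grid_phase, grid_amp)
        assert series.n_windows == 6
        np.testing.assert_array_equal(
            series.excluded, [False, False, False, True, False, False]
        )

    def test_clean_trace_unmasked_and_infinite_threshold(self):
        trace = generate_background(SynthConfig(16.0, 256.0, seed=6))
        grid = FrequencyGrid(np.array([4.0]), 4, 4, 1)
        amp = FrequencyGrid(np.array([32.0]), 32, 32, 1)
        assert not pac_windows(trace, grid, amp).excluded.any()
        masked = artifact_mask(trace, [(0.0, 8.0), (8.0, 16.0)], np.inf)
        assert not masked.any()


def _const_series(mi_value, n_windows, excluded=None):
    grid_p = FrequencyGrid(np.array([4.0, 8.0]), 4, 8, 1)
    grid_a = FrequencyGrid(np.array([32.0, 64.0]), 32, 64, 1)
    comods = [
        Comodulogram(np.full((2, 2), mi_value * (w + 1)), grid_p, grid_a)
        for w in range(n_windows)
    ]
    return PACWindowSeries(
        starts=np.arange(n_windows) * 4.0,
        comodulograms=comods,
        window_s=4.0,
        excluded=np.array(excluded or [False] * n_windows),
        reliable_phase_rows=np.array([True, True]),
    )


class TestMeanPac:
    def test_identical_windows_segment_mean_is_grid_mean(self):
        series = _const_series(0.02, 4)
        series.comodulograms = [series.comodulograms[0]] * 4
        ev = DischargeEvent("c", 0.0, 16.0)
        seg = segment_epochs(ev, (0.0, 16.0))
        out = mean_pac(series, seg)
        assert out.mean_mi["onset"] == pytest.approx(0.02)

    def test_masked_window_excluded_from_mean(self):
        series = _const_series(0.01, 2, excluded=[False, True])
        ev = DischargeEvent("c", 0.0, 16.0)
        seg = segment_epochs(ev, (0.0, 16.0))
        out = mean_pac(series, seg)
        # onset segment [0, 8) holds both windows; only the unmasked first
        # window (grid mean 0.01) survives
        assert out.mean_mi["onset"] == pytest.approx(0.01)
        assert out.n_windows["onset"] == 1

    def test_all_masked_segment_missing(self):
        series = _const_series(0.01, 2, excluded=[True, True])
        seg = segment_epochs(DischargeEvent("c", 0.0, 16.0), (0.0, 16.0))
        out = mean_pac(series, seg)
        assert out.missing("onset")
        assert np.isnan(out.mean_mi["onset"])


class TestWpc:
    def test_identical_inputs_fully_coherent(self):
        tr = generate_background(SynthConfig(20.0, 256.0, seed=7))
        cmap = wpc(tr, tr.copy(), make_log_grid(1.0, 64.0, 2))
        for r in cmap.rho:
            if r.size:
                np.testing.assert_allclose(r, 1.0, atol=1e-6)

    def test_scaled_delayed_tone_fully_coherent(self, tone_trace):
        a = tone_trace(16.0, fs=256.0, duration=16.0)
        b = tone_trace(16.0, fs=256.0, duration=16.0, amps=[0.3], phases=[1.1])
        cmap = wpc(a, b, FrequencyGrid(np.array([16.0]), 16, 16, 1))
        # edge windows sit inside the wavelet cone of influence
        np.testing.assert_allclose(cmap.rho[0][1:-1], 1.0, atol=1e-6)
        np.testing.assert_allclose(cmap.rho[0], 1.0, atol=1e-3)

    def test_symmetric_and_scale_invariant(self):
        a = generate_background(SynthConfig(16.0, 256.0, seed=8))
        b = generate_background(SynthConfig(16.0, 256.0, seed=9))
        grid = make_log_grid(2.0, 32.0, 2)
        r_ab = wpc(a, b, grid)
        r_ba = wpc(b, a, grid)
        r_scaled = wpc(Trace(5.0 * a.samples, a.fs), b, grid)
        for k in range(len(grid)):
            np.testing.assert_allclose(r_ab.rho[k], r_ba.rho[k], atol=1e-12)
            np.testing.assert_allclose(r_ab.rho[k], r_scaled.rho[k], atol=1e-9)

    def test_misaligned_traces_raise(self):
        a = Trace(np.zeros(100), fs=100.0)
        b = Trace(np.zeros(100), fs=200.0)
        with pytest.raises(AlignmentError):
            wpc(a, b)

    def test_null_bias_helper(self):
        assert wpc_null_bias(1) == pytest.approx(np.sqrt(np.pi / 4))
        with pytest.raises(InvalidArgumentError):
            wpc_null_bias(0)
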