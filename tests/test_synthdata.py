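"""Generator contracts: determinism, planted statistics, ground truth."""

import numpy as np
import pytest
from scipy import signal as sps

from kindleictal.errors import AliasingError, ConflictError, InvalidArgumentError
from kindleictal.events import HYP, LVF
from kindleictal.synthdata import (
    CouplingSpec,
    DischargeSpec,
    SliceEventSpec,
    SynthConfig,
    generate_background,
    generate_coherent_pair,
    generate_pac_signal,
    generate_slice_trace,
    inject_artifact,
    inject_discharge,
)


class TestBackground:
    def test_length_and_sd(self):
        tr = generate_background(SynthConfig(10.0, 1000.0, seed=7, background_sd=1.0))
        assert tr.n == 10_000
        assert 0.95 <= tr.samples.std() <= 1.05
        assert abs(tr.samples.mean()) < 1e-9

    def test_seed_determinism(self):
        cfg = SynthConfig(5.0, 1000.0, seed=11)
        a = generate_background(cfg)
        b = generate_background(cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_one_over_f_power_ratio(self):
        # alpha = 1: power at 4 Hz exceeds power at 64 Hz by ~16x
        tr = generate_background(SynthConfig(400.0, 1000.0, seed=3))
        f, p = sps.welch(tr.samples, fs=1000.0, nperseg=4096)
        p4 = p[np.argmin(np.abs(f - 4.0))]
        p64 = p[np.argmin(np.abs(f - 64.0))]
        assert 11.0 < p4 / p64 < 22.0

    def test_invalid_config(self):
        with pytest.raises(InvalidArgumentError):
            SynthConfig(-1.0, 1000.0)
        with pytest.raises(InvalidArgumentError):
            SynthConfig(10.0, 0.0)


class TestInjectDischarge:
    def test_lvf_window_sd_ratio(self):
        cfg = SynthConfig(60.0, 1000.0, seed=5)
        tr = generate_background(cfg)
        spec = DischargeSpec(onset_time=20.0, total_duration=20.0, onset_class=LVF,
                             lvf_attenuation=0.4, lvf_length=2.0)
        out, truth = inject_discharge(tr, spec, seed=1)
        lvf = out.samples[20_000:22_000]
        preceding = out.samples[15_000:20_000]
        ratio = lvf.std() / preceding.std()
        assert 0.36 <= ratio <= 0.44
        assert truth.onset_class == LVF

    def test_hyp_first_second_spike_cluster(self):
        cfg = SynthConfig(60.0, 1000.0, seed=6)
        tr = generate_background(cfg)
        out, truth = inject_discharge(
            tr, DischargeSpec(onset_time=20.0, total_duration=15.0, onset_class=HYP),
            seed=2,
        )
        sd0 = tr.samples.std()
        first_sec = out.samples[20_000:21_000]
        peaks, props = sps.find_peaks(np.abs(first_sec), height=2.0 * sd0, distance=30)
        assert peaks.size >= 3

    def test_ground_truth_duration_exact(self):
        tr = generate_background(SynthConfig(60.0, 1000.0, seed=7))
        _, truth = inject_discharge(
            tr, DischargeSpec(onset_time=10.0, total_duration=30.0), seed=3
        )
        assert truth.duration_s == 30.0

    def test_overlap_raises_conflict(self):
        tr = generate_background(SynthConfig(80.0, 1000.0, seed=8))
        out, first = inject_discharge(
            tr, DischargeSpec(onset_time=10.0, total_duration=30.0), seed=4
        )
        with pytest.raises(ConflictError):
            inject_discharge(
                out, DischargeSpec(onset_time=25.0, total_duration=20.0),
                seed=5, existing=[first],
            )

    def test_spec_invariants_enforced(self):
        with pytest.raises(InvalidArgumentError):
            DischargeSpec(onset_time=0.0, total_duration=8.0)
        with pytest.raises(InvalidArgumentError):
            DischargeSpec(onset_time=0.0, total_duration=20.0, lvf_length=0.2)
        with pytest.raises(InvalidArgumentError):
            DischargeSpec(onset_time=0.0, total_duration=20.0, spike_amplitude=1.0)


class TestPacSignal:
    def _carrier_envelope(self, trace, f_amp):
        # Hilbert envelope of the high-passed carrier keeps all modulation
        # sidebands (a constant-Q wavelet row would smooth them away)
        sos = sps.butter(4, f_amp / 2, "highpass", fs=trace.fs, output="sos")
        carrier = sps.sosfiltfilt(sos, trace.samples)
        env = np.abs(sps.hilbert(carrier))
        return env[trace.n // 4 : -trace.n // 4]

    def test_depth_zero_envelope_constant(self):
        cfg = SynthConfig(20.0, 1000.0, seed=9, background_sd=0.0)
        tr, _ = generate_pac_signal(CouplingSpec(8.0, 80.0, depth=0.0), cfg)
        env = self._carrier_envelope(tr, 80.0)
        assert env.std() / env.mean() < 0.05

    def test_depth_one_envelope_vanishes_at_antiphase(self):
        cfg = SynthConfig(20.0, 1000.0, seed=9, background_sd=0.0)
        tr, _ = generate_pac_signal(CouplingSpec(8.0, 80.0, depth=1.0), cfg)
        env = self._carrier_envelope(tr, 80.0)
        assert env.min() < 0.1 * env.max()

    def test_aliasing_guard(self):
        with pytest.raises(AliasingError):
            generate_pac_signal(CouplingSpec(8.0, 600.0), SynthConfig(10.0, 1000.0))


class TestCoherentPair:
    def test_same_seed_identical_pair(self):
        cfg = SynthConfig(10.0, 500.0, seed=12)
        a1, b1 = generate_coherent_pair(16.0, 0.7, cfg)
        a2, b2 = generate_coherent_pair(16.0, 0.7, cfg)
        np.testing.assert_array_equal(a1.samples, a2.samples)
        np.testing.assert_array_equal(b1.samples, b2.samples)

    def test_full_lock_is_scaled_copy(self):
        cfg = SynthConfig(10.0, 500.0, seed=13)
        a, b = generate_coherent_pair(16.0, 1.0, cfg, phase_lag=0.0, gain=0.5)
        np.testing.assert_allclose(b.samples, 0.5 * a.samples, atol=1e-12)


class TestSliceTrace:
    def test_spw_train_counts_and_ranges(self):
        cfg = SynthConfig(60.0, 2000.0, seed=14, background_sd=0.05,
                          spectral_exponent=0.0)
        _, truth = generate_slice_trace(
            [SliceEventSpec("SPW", amplitude=0.15, base_duration=0.05, rate=1.0)], cfg
        )
        assert 58 <= len(truth) <= 62
        durations = truth.base_duration_s
        assert ((durations >= 0.02) & (durations <= 0.2)).all()
        assert truth.meets_criteria.all()

    def test_ictal_event_arithmetic(self):
        cfg = SynthConfig(300.0, 1000.0, seed=15, background_sd=0.05,
                          spectral_exponent=0.0)
        _, truth = generate_slice_trace(
            [SliceEventSpec("ICTAL", amplitude=1.5, base_duration=40.0,
                            interevent_interval=120.0)],
            cfg,
        )
        assert len(truth) == 2

    def test_subthreshold_interictal_flagged(self):
        cfg = SynthConfig(60.0, 1000.0, seed=16, background_sd=0.05,
                          spectral_exponent=0.0)
        _, truth = generate_slice_trace(
            [SliceEventSpec("INTERICTAL", amplitude=0.4, base_duration=0.3, rate=0.3)],
            cfg,
        )
        assert len(truth) > 0
        assert not truth.meets_criteria.any()

    def test_overlapping_ictal_raises(self):
        cfg = SynthConfig(100.0, 1000.0, seed=17, background_sd=0.05)
        with pytest.raises(ConflictError):
            generate_slice_trace(
                [SliceEventSpec("ICTAL", amplitude=1.5, base_duration=40.0,
                                interevent_interval=30.0)],
                cfg,
            )


class TestInjectArtifact:
    def test_transient_magnitude_and_location(self):
        tr = generate_background(SynthConfig(30.0, 1000.0, seed=18))
        sd0 = tr.samples.std()
        out, times = inject_artifact(tr, [12.0], magnitude=10.0, width=0.2)
        assert times == [12.0]
        seg = out.samples[11_900:12_300]
        assert np.max(np.abs(seg)) >= 10.0 * sd0

    def test_empty_times_identity(self):
        tr = generate_background(SynthConfig(5.0, 1000.0, seed=19))
        out, times = inject_artifact(tr, [])
        assert times == []
        np.testing.assert_array_equal(out.samples, tr.samples)

    def test_out_of_range_time_raises(self):
        tr = generate_background(SynthConfig(5.0, 1000.0, seed=20))
        with pytest.raises(InvalidArgumentError):
            inject_artifact(tr, [99.0])
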