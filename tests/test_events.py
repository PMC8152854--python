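"""Discharge recognition, onset classification, in-vitro detectors, epochs."""

import numpy as np
import pytest

from kindleictal.errors import DataError, InvalidArgumentError, UnitError
from kindleictal.events import (
    HYP,
    LVF,
    DetectionParams,
    DischargeEvent,
    classify_events,
    detect_discharges,
    detect_interictal,
    detect_spw,
    quantify_lvf,
    segment_epochs,
)
from kindleictal.signal_io import Trace
from kindleictal.synthdata import (
    DischargeSpec,
    SynthConfig,
    generate_background,
    generate_discharge_recording,
)


@pytest.fixture(scope="module")
def planted_recording():
    cfg = SynthConfig(duration=90.0, fs=1000.0, seed=23)
    spec = DischargeSpec(onset_time=35.0, total_duration=30.0, onset_class=LVF,
                         lvf_attenuation=0.4, lvf_length=2.0)
    trace, truths = generate_discharge_recording(cfg, [spec])
    return trace, truths[0]


class TestDetectDischarges:
    def test_pure_background_yields_nothing(self):
        tr = generate_background(SynthConfig(60.0, 1000.0, seed=21))
        assert detect_discharges(tr) == []

    def test_flat_trace_yields_nothing(self):
        assert detect_discharges(Trace(np.zeros(60_000), fs=1000.0)) == []

    def test_nan_raises_data_error(self):
        x = np.zeros(60_000)
        x[100] = np.nan
        with pytest.raises(DataError):
            detect_discharges(Trace(x, fs=1000.0))

    def test_short_trace_rejected(self):
        tr = generate_background(SynthConfig(20.0, 1000.0, seed=22))
        with pytest.raises(InvalidArgumentError):
            detect_discharges(tr)

    def test_planted_discharge_recovered(self, planted_recording):
        trace, truth = planted_recording
        events = detect_discharges(trace)
        assert len(events) == 1
        assert abs(events[0].onset_s - truth.onset_s) <= 0.5
        assert abs(events[0].duration_s - 30.0) <= 1.0

    def test_events_sorted_nonoverlapping(self):
        cfg = SynthConfig(duration=180.0, fs=1000.0, seed=24)
        specs = [
            DischargeSpec(onset_time=35.0, total_duration=20.0, onset_class=HYP),
            DischargeSpec(onset_time=90.0, total_duration=25.0, onset_class=LVF),
        ]
        trace, _ = generate_discharge_recording(cfg, specs)
        events = detect_discharges(trace)
        assert len(events) == 2
        assert events[0].onset_s < events[1].onset_s
        assert events[0].termination_s <= events[1].onset_s

    def test_amplitude_factor_monotone(self, planted_recording):
        trace, _ = planted_recording
        counts = [
            len(detect_discharges(trace, DetectionParams(amplitude_factor=f)))
            for f in (1.5, 2.0, 3.0, 6.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestClassifyOnset:
    def test_planted_lvf_classified(self, planted_recording):
        trace, truth = planted_recording
        events = classify_events(trace, detect_discharges(trace))
        assert events[0].onset_class == LVF
        assert events[0].lvf_metrics is not None
        assert events[0].lvf_metrics.normalized_sd_pct <= 65.0

    def test_planted_hyp_classified(self):
        cfg = SynthConfig(duration=80.0, fs=1000.0, seed=25)
        spec = DischargeSpec(onset_time=35.0, total_duration=20.0, onset_class=HYP)
        trace, _ = generate_discharge_recording(cfg, [spec])
        events = classify_events(trace, detect_discharges(trace))
        assert len(events) == 1
        assert events[0].onset_class == HYP

    def test_mild_attenuation_not_lvf(self):
        # 90 % of preceding amplitude exceeds the 65 % rule
        cfg = SynthConfig(duration=80.0, fs=1000.0, seed=26)
        spec = DischargeSpec(onset_time=35.0, total_duration=20.0, onset_class=LVF,
                             lvf_attenuation=0.9, lvf_length=2.0)
        trace, _ = generate_discharge_recording(cfg, [spec])
        events = classify_events(trace, detect_discharges(trace))
        assert len(events) == 1
        assert events[0].onset_class != LVF


class TestQuantifyLvf:
    def test_identical_windows_give_100_percent(self):
        rng = np.random.default_rng(27)
        x = rng.standard_normal(30_000)
        x[12_000:14_000] = x[10_000:12_000]  # LVF window duplicates preceding
        tr = Trace(x, fs=1000.0)
        ev = DischargeEvent("c", 12.0, 25.0)
        m = quantify_lvf(tr, ev, lvf_window=(12.0, 2.0))
        # band-pass filtering mixes in neighbouring samples, so the two
        # windows match to filter leakage, not bit-exactly
        assert m.normalized_sd_pct == pytest.approx(100.0, abs=0.1)

    def test_zero_amplitude_window_gives_zero(self):
        rng = np.random.default_rng(28)
        x = rng.standard_normal(30_000)
        x[12_000:14_000] = 0.0
        tr = Trace(x, fs=1000.0)
        m = quantify_lvf(tr, DischargeEvent("c", 12.0, 25.0), lvf_window=(12.0, 2.0))
        assert m.normalized_sd_pct < 2.0  # band-pass edge leakage only

    def test_noiseless_attenuation_recovered(self):
        cfg = SynthConfig(60.0, 1000.0, seed=29)
        from kindleictal.synthdata import inject_discharge

        tr = generate_background(cfg)
        spec = DischargeSpec(onset_time=20.0, total_duration=20.0, onset_class=LVF,
                             lvf_attenuation=0.5, lvf_length=2.0)
        out, truth = inject_discharge(tr, spec, seed=6)
        m = quantify_lvf(out, truth, lvf_window=(20.0, 2.0))
        assert 45.0 <= m.normalized_sd_pct <= 55.0

    def test_short_window_rejected(self, planted_recording):
        trace, truth = planted_recording
        with pytest.raises(InvalidArgumentError):
            quantify_lvf(trace, truth, lvf_window=(35.0, 0.3))


class TestInvitroUnits:
    def test_interictal_requires_mv(self):
        tr = Trace(np.zeros(10_000), fs=1000.0, units="V")
        with pytest.raises(UnitError):
            detect_interictal(tr)

    def test_short_trace_warns_and_runs(self):
        tr = Trace(np.random.default_rng(30).standard_normal(20_000) * 0.01,
                   fs=1000.0, units="mV")
        with pytest.warns(UserWarning, match="incidence"):
            out = detect_spw(tr)
        assert len(out) == 0


class TestSegmentEpochs:
    def test_canonical_event_partition(self):
        ev = DischargeEvent("c", 100.0, 160.0)
        seg = segment_epochs(ev, (0.0, 1000.0))
        assert seg.intervals["preictal"] == (92.0, 100.0)
        assert seg.intervals["onset"] == (100.0, 108.0)
        assert seg.intervals["ictal"] == (108.0, 152.0)
        assert seg.intervals["offset"] == (152.0, 160.0)
        assert seg.intervals["postictal"] == (160.0, 168.0)
        assert not any(seg.truncated.values())
        # exact partition of [onset-8, termination+8)
        bounds = [seg.intervals[n] for n in
                  ("preictal", "onset", "ictal", "offset", "postictal")]
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert b == c
        assert bounds[0][0] == 92.0 and bounds[-1][1] == 168.0

    def test_sixteen_second_event_has_empty_middle(self):
        seg = segment_epochs(DischargeEvent("c", 100.0, 116.0), (0.0, 1000.0))
        assert seg.intervals["ictal"] is None
        assert seg.middle_empty
        assert seg.truncated["ictal"]

    def test_onset_near_trace_start_truncates_preictal(self):
        seg = segment_epochs(DischargeEvent("c", 4.0, 30.0), (0.0, 1000.0))
        assert seg.intervals["preictal"] == (0.0, 4.0)
        assert seg.truncated["preictal"]
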