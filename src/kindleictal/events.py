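"""Detection and classification of electrographic events.

In-vivo rules (intracranial EEG): a spontaneous discharge is a run of
repetitive spikes with amplitudes about twice the background signal lasting
at least 10 s; termination is the last suprathreshold spike followed by
signal suppression.  Onsets are classed as LVF (low-voltage fast: abrupt
attenuation of background to <= 65 % of the preceding signal for 0.5-5 s
before repetitive spiking), HYP (hypersynchronous: a cluster of >= 3
abruptly arising large spikes within the first second), INCREMENTAL
(spike amplitude ramps up from baseline), or UNCLASSIFIED.

In-vitro rules (slice field potentials): sharp waves (SPWs) are ~2x
background events with 20-200 ms base durations at 0.3-4 events/s
(measured over 1-min segments); interictal spikes have absolute amplitudes
>= 0.5 mV, base durations 200-600 ms and incidences of 2-5 events/10 s;
ictal discharges have peak amplitudes >= 1 mV and a trace is classed
ictal-bearing only when mean event duration >= 30 s and mean interevent
interval >= 90 s.

Amplitude thresholds for the in-vivo rules reference a rolling robust
background level (MAD scaled to SD) computed from the 2-200 Hz filtered
signal, so the spikes being detected do not inflate their own reference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DataError, InvalidArgumentError, UnitError
from .signal_io import Trace, bandpass_bessel

__all__ = [
    "LVF",
    "HYP",
    "INCREMENTAL",
    "UNCLASSIFIED",
    "LVFMetrics",
    "DischargeEvent",
    "DetectionParams",
    "detect_discharges",
    "classify_onset",
    "classify_events",
    "quantify_lvf",
    "detect_spw",
    "detect_interictal",
    "detect_ictal_invitro",
    "IctalDetection",
    "EpochSegmentation",
    "segment_epochs",
]

LVF = "LVF"
HYP = "HYP"
INCREMENTAL = "INCREMENTAL"
UNCLASSIFIED = "UNCLASSIFIED"

LVF_MAX_NORMALIZED_SD = 65.0  # percent of preceding signal
LVF_MIN_LEN_S, LVF_MAX_LEN_S = 0.5, 5.0


@dataclass
class LVFMetrics:
    """SD quantification of a low-voltage fast onset component."""

    lvf_start_s: float
    lvf_length_s: float
    sd_lvf: float
    sd_preceding: float

    @property
    def normalized_sd_pct(self) -> float:
        """100 * SD(LVF window) / SD(preceding window)."""
        if self.sd_preceding == 0:
            return float("nan")
        return 100.0 * self.sd_lvf / self.sd_preceding


@dataclass
class DischargeEvent:
    """One detected (or planted) electrographic discharge."""

    channel: str
    onset_s: float
    termination_s: float
    onset_class: str = UNCLASSIFIED
    lvf_metrics: LVFMetrics | None = None
    motor_stage: int | None = None  # metadata only, never used by detection
    attrs: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.termination_s - self.onset_s


@dataclass
class DetectionParams:
    """Tunable constants of the discharge recognition rule."""

    background_window_s: float = 30.0
    amplitude_factor: float = 2.0
    min_duration_s: float = 10.0
    spike_gap_s: float = 2.0
    suppression_check_s: float = 2.0
    suppression_factor: float = 1.5
    band: tuple[float, float] = (2.0, 200.0)
    min_spike_separation_s: float = 0.03

    def __post_init__(self) -> None:
        for name in (
            "background_window_s",
            "amplitude_factor",
            "min_duration_s",
            "spike_gap_s",
            "suppression_check_s",
        ):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Background level
# ---------------------------------------------------------------------------

# Typical peak amplitude of Gaussian-like background in SD units (its 98th
# percentile).  The "2x the background signals" rule compares spike
# amplitude against the background's visible amplitude, not its SD: peaks
# of the background itself routinely reach 2-3 SDs, so thresholding at
# 2 x SD would fire continuously on pure background.
BACKGROUND_PEAK_FACTOR = 2.33


def _mad_sd(x: np.ndarray) -> float:
    """Robust SD via the median absolute deviation (Gaussian scaling)."""
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def _quiet_background(x: np.ndarray, fs: float) -> float:
    """Whole-trace quiet background SD: 25th percentile of 1-s block MADs.

    The quietest quarter of the blocks estimates the discharge-free
    baseline even when most of the trace is covered by events.
    """
    block = max(2, int(round(fs)))
    n_blocks = max(1, x.size // block)
    sds = [_mad_sd(x[i * block : (i + 1) * block]) for i in range(n_blocks)]
    return float(max(np.percentile(sds, 25), 1e-12))


def _short_window_sd(x: np.ndarray, fs: float, win_s: float = 0.25) -> np.ndarray:
    """Centred rolling SD with a ``win_s`` rectangular window."""
    w = max(2, int(round(win_s * fs)))
    c1 = np.convolve(x, np.ones(w) / w, mode="same")
    c2 = np.convolve(x**2, np.ones(w) / w, mode="same")
    return np.sqrt(np.maximum(c2 - c1**2, 0.0))


# ---------------------------------------------------------------------------
# In-vivo discharge detection
# ---------------------------------------------------------------------------


def detect_discharges(
    trace: Trace, params: DetectionParams = DetectionParams()
) -> list[DischargeEvent]:
    """Detect spontaneous discharges on a single channel.

    Spikes are peaks of the 2-200 Hz filtered signal whose amplitude
    exceeds ``amplitude_factor`` times the background amplitude, where the
    background amplitude is the robust typical peak height
    (:data:`BACKGROUND_PEAK_FACTOR` x MAD-scaled SD) of a pre-event
    window, so a long discharge never inflates its own threshold.  Runs of
    spikes separated by gaps <= ``spike_gap_s`` form candidate events, kept
    when they last at least ``min_duration_s``.  When a pre-spike window
    shows the LVF attenuation signature the event onset is anchored at the
    attenuation crossing (recorded in ``attrs``), otherwise at the first
    spike.
    """
    if np.any(~np.isfinite(trace.samples)):
        raise DataError("trace contains NaN or infinite samples")
    if trace.duration <= params.background_window_s:
        raise InvalidArgumentError(
            f"trace ({trace.duration:g} s) must exceed background_window_s "
            f"({params.background_window_s:g} s)"
        )
    low, high = params.band
    high = min(high, 0.45 * trace.fs)
    filt = bandpass_bessel(trace, low, high)
    x = filt.samples
    if np.all(x == 0):
        return []
    bg0 = _quiet_background(x, trace.fs)

    def threshold(bg_sd: float) -> float:
        return params.amplitude_factor * BACKGROUND_PEAK_FACTOR * bg_sd

    peaks, _ = sps.find_peaks(
        np.abs(x),
        height=threshold(bg0),
        distance=max(1, int(round(params.min_spike_separation_s * trace.fs))),
    )
    if peaks.size == 0:
        return []
    t_peaks = trace.t0 + peaks / trace.fs

    # group spikes into trains
    gaps = np.diff(t_peaks)
    breaks = np.flatnonzero(gaps > params.spike_gap_s)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [t_peaks.size - 1]])

    sd_short = _short_window_sd(x, trace.fs)
    events: list[DischargeEvent] = []
    prev_end = trace.t0
    for a, b in zip(starts, stops):
        t_first, t_last = t_peaks[a], t_peaks[b]
        # pre-event background: MAD of the window before the train start,
        # clear of the previous event
        pre_lo = max(prev_end, t_first - params.background_window_s)
        i_lo, i_hi = filt.index_of(pre_lo), filt.index_of(t_first - 0.5)
        bg_sd = _mad_sd(x[i_lo:i_hi]) if i_hi - i_lo > int(2 * trace.fs) else bg0
        bg_sd = bg_sd or bg0
        keep = np.abs(x[peaks[a : b + 1]]) >= threshold(bg_sd)
        if not np.any(keep):
            continue
        tk = t_peaks[a : b + 1][keep]
        t_first, t_last = tk[0], tk[-1]
        onset, lvf_info = _refine_lvf_onset(filt, sd_short, bg_sd, t_first)
        termination = t_last + 0.02
        prev_end = termination
        if termination - onset < params.min_duration_s:
            continue
        suppressed = _check_suppression(filt, sd_short, bg_sd, termination, params)
        attrs = {
            "first_spike_s": float(t_first),
            "n_spikes": int(np.sum(keep)),
            "suppression_confirmed": bool(suppressed),
            "peak_times": tk,
            "peak_amps": np.abs(x[peaks[a : b + 1]][keep]),
            "background_sd": float(bg_sd),
        }
        if lvf_info is not None:
            attrs["lvf_start_s"], attrs["lvf_length_s"] = lvf_info
        events.append(
            DischargeEvent(trace.channel, float(onset), float(termination), attrs=attrs)
        )

    # enforce sorted, non-overlapping events
    events.sort(key=lambda e: e.onset_s)
    merged: list[DischargeEvent] = []
    for ev in events:
        if merged and ev.onset_s < merged[-1].termination_s:
            prev = merged[-1]
            merged[-1] = replace(
                prev, termination_s=max(prev.termination_s, ev.termination_s)
            )
        else:
            merged.append(ev)
    return merged


def _refine_lvf_onset(
    filt: Trace, sd_short: np.ndarray, bg_sd: float, t_first_spike: float
) -> tuple[float, tuple[float, float] | None]:
    """Anchor the onset at the LVF attenuation crossing when present.

    Scans the seconds before the first suprathreshold spike for a
    contiguous run where the 0.25-s rolling SD stays <= 65 % of the
    pre-event background.  Sub-threshold incremental spikes often separate
    the attenuated window from the first *detected* spike, so the run need
    not touch the spike: the latest run of at least ``LVF_MIN_LEN_S``
    ending within ``ramp_allowance`` of it moves the onset to its start.
    """
    fs = filt.fs
    ramp_allowance = 3.5  # s of incremental spiking tolerated after the LVF
    i_spike = filt.index_of(t_first_spike)
    i_hi = max(0, i_spike - int(round(0.1 * fs)))
    i_lo = max(0, i_spike - int(round((LVF_MAX_LEN_S + ramp_allowance + 0.5) * fs)))
    if i_hi - i_lo < int(LVF_MIN_LEN_S * fs):
        return t_first_spike, None
    attenuated = sd_short[i_lo:i_hi] <= (LVF_MAX_NORMALIZED_SD / 100.0) * bg_sd
    attenuated = _close_gaps(attenuated, int(round(0.3 * fs)))
    edges = np.diff(attenuated.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if attenuated[0]:
        starts.insert(0, 0)
    if attenuated[-1]:
        stops.append(attenuated.size)
    min_run = int(LVF_MIN_LEN_S * fs)
    for a, b in zip(reversed(starts), reversed(stops)):  # latest run first
        if b - a < min_run:
            continue
        t_end = filt.t0 + (i_lo + b) / fs
        if t_first_spike - t_end > ramp_allowance:
            break  # runs further back belong to pre-event background dips
        t_start = filt.t0 + (i_lo + a) / fs
        length = min((b - a) / fs, LVF_MAX_LEN_S)
        return t_start, (float(t_start), float(length))
    return t_first_spike, None


def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill False runs shorter than ``max_gap`` between True runs.

    Short-window SD estimates fluctuate on a 1/f background, so a single
    attenuated interval shows up as runs split by brief excursions.
    """
    out = mask.copy()
    edges = np.diff(mask.astype(np.int8))
    gap_starts = np.flatnonzero(edges == -1) + 1
    gap_stops = np.flatnonzero(edges == 1) + 1
    for a in gap_starts:
        nxt = gap_stops[gap_stops > a]
        if nxt.size and nxt[0] - a <= max_gap:
            out[a : nxt[0]] = True
    return out


def _check_suppression(
    filt: Trace,
    sd_short: np.ndarray,
    bg_sd: float,
    termination: float,
    params: DetectionParams,
) -> bool:
    i0 = filt.index_of(termination + 0.05)
    i1 = min(filt.n, i0 + int(round(params.suppression_check_s * filt.fs)))
    if i1 - i0 < 2:
        return False
    return bool(np.median(sd_short[i0:i1]) < params.suppression_factor * bg_sd)


# ---------------------------------------------------------------------------
# Onset classification
# ---------------------------------------------------------------------------


def classify_onset(
    trace: Trace, event: DischargeEvent, params: DetectionParams = DetectionParams()
) -> str:
    """Classify a discharge onset as LVF / HYP / INCREMENTAL / UNCLASSIFIED."""
    if event.onset_s < trace.t0 - 1e-9 or event.termination_s > trace.t_end + 1e-9:
        raise InvalidArgumentError("event lies outside the trace extent")

    # LVF: attenuated window (<= 65 % of preceding) before repetitive spikes
    lvf_win = _lvf_window(trace, event, params)
    if lvf_win is not None:
        metrics = quantify_lvf(trace, event, lvf_win)
        if metrics.normalized_sd_pct <= LVF_MAX_NORMALIZED_SD:
            return LVF

    peak_times, peak_amps, bg_sd = _event_spikes(trace, event, params)
    if peak_times.size == 0:
        return UNCLASSIFIED
    spike_start = event.attrs.get("first_spike_s", event.onset_s)
    first_sec = (peak_times >= spike_start) & (peak_times < spike_start + 1.0)
    mid_lo = event.onset_s + 0.2 * event.duration_s
    mid_hi = event.onset_s + 0.8 * event.duration_s
    steady = (peak_times >= mid_lo) & (peak_times < mid_hi)
    steady_amp = np.median(peak_amps[steady]) if steady.any() else np.median(peak_amps)

    n_large_first = int(np.sum(first_sec & (peak_amps >= 2.0 * bg_sd)))
    first_amp = np.median(peak_amps[first_sec]) if first_sec.any() else 0.0

    if n_large_first >= 3 and first_amp >= 0.6 * steady_amp:
        return HYP

    # INCREMENTAL: spike amplitude ramps up from near baseline
    early = peak_times < spike_start + 3.0
    if early.sum() >= 3 and steady_amp > 0:
        slope = np.polyfit(peak_times[early], peak_amps[early], 1)[0]
        if slope > 0 and first_amp < 0.6 * steady_amp:
            return INCREMENTAL
    return UNCLASSIFIED


def classify_events(
    trace: Trace, events: list[DischargeEvent], params: DetectionParams = DetectionParams()
) -> list[DischargeEvent]:
    """Return events with ``onset_class`` (and LVF metrics) filled in."""
    out = []
    for ev in events:
        cls = classify_onset(trace, ev, params)
        metrics = None
        if cls == LVF:
            metrics = quantify_lvf(trace, ev, _lvf_window(trace, ev, params))
        out.append(replace(ev, onset_class=cls, lvf_metrics=metrics))
    return out


def _lvf_window(
    trace: Trace, event: DischargeEvent, params: DetectionParams
) -> tuple[float, float] | None:
    """(start, length) of the candidate LVF window, if any."""
    if "lvf_start_s" in event.attrs:
        return event.attrs["lvf_start_s"], event.attrs["lvf_length_s"]
    first_spike = event.attrs.get("first_spike_s")
    if first_spike is None:
        # ground-truth events: assume spiking begins after any LVF component;
        # find the first suprathreshold spike after onset
        t, a, bg = _event_spikes(trace, event, params)
        first_spike = float(t[0]) if t.size else None
    if first_spike is None:
        return None
    length = first_spike - event.onset_s
    if LVF_MIN_LEN_S <= length <= LVF_MAX_LEN_S:
        return event.onset_s, length
    return None


def _event_spikes(
    trace: Trace, event: DischargeEvent, params: DetectionParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Suprathreshold peaks within the event (times, |amplitudes|, bg SD)."""
    if "peak_times" in event.attrs:
        return (
            np.asarray(event.attrs["peak_times"]),
            np.asarray(event.attrs["peak_amps"]),
            float(event.attrs["background_sd"]),
        )
    low, high = params.band
    seg = trace.slice(
        max(trace.t0, event.onset_s - 5.0), min(trace.t_end, event.termination_s + 1.0)
    )
    filt = bandpass_bessel(seg, low, min(high, 0.45 * trace.fs))
    pre = trace.slice(
        max(trace.t0, event.onset_s - 10.0), max(trace.t0 + 1.0 / trace.fs, event.onset_s)
    )
    bg_sd = _mad_sd(bandpass_bessel(pre, low, min(high, 0.45 * trace.fs)).samples)
    bg_sd = bg_sd or _mad_sd(filt.samples)
    peaks, props = sps.find_peaks(
        np.abs(filt.samples),
        height=params.amplitude_factor * bg_sd,
        distance=max(1, int(round(params.min_spike_separation_s * trace.fs))),
    )
    t = filt.t0 + peaks / filt.fs
    keep = (t >= event.onset_s) & (t < event.termination_s)
    return t[keep], props["peak_heights"][keep], bg_sd


# ---------------------------------------------------------------------------
# LVF quantification
# ---------------------------------------------------------------------------


def quantify_lvf(
    trace: Trace,
    event: DischargeEvent,
    lvf_window: tuple[float, float] | None = None,
) -> LVFMetrics:
    """SD of the LVF window as a percentage of the preceding window.

    Both windows are taken from the 2-200 Hz band-passed signal (flattening
    DC-like shifts that ride under the LVF component); the preceding window
    has the same length as the LVF window and ends at its start.
    """
    if lvf_window is None:
        if event.lvf_metrics is not None:
            lvf_window = (event.lvf_metrics.lvf_start_s, event.lvf_metrics.lvf_length_s)
        elif "lvf_start_s" in event.attrs:
            lvf_window = (event.attrs["lvf_start_s"], event.attrs["lvf_length_s"])
        else:
            raise InvalidArgumentError("no LVF window available for this event")
    start, length = lvf_window
    if length < LVF_MIN_LEN_S:
        raise InvalidArgumentError(f"LVF window must be >= {LVF_MIN_LEN_S} s, got {length} s")
    if start - length < trace.t0:
        raise InvalidArgumentError("no equal-length preceding window available")
    seg = trace.slice(max(trace.t0, start - length - 2.0), min(trace.t_end, start + length + 2.0))
    filt = bandpass_bessel(seg, 2.0, min(200.0, 0.45 * trace.fs))
    i0 = filt.index_of(start)
    n = int(round(length * trace.fs))
    lvf = filt.samples[i0 : i0 + n]
    pre = filt.samples[max(0, i0 - n) : i0]
    return LVFMetrics(
        lvf_start_s=float(start),
        lvf_length_s=float(length),
        sd_lvf=float(np.std(lvf)),
        sd_preceding=float(np.std(pre)),
    )


# ---------------------------------------------------------------------------
# In-vitro detectors
# ---------------------------------------------------------------------------


def _event_table(rows: list[dict], channel: str) -> pd.DataFrame:
    cols = [
        "event_id",
        "channel",
        "kind",
        "onset_s",
        "termination_s",
        "peak_amplitude",
        "base_duration_s",
        "params_json",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df.insert(0, "event_id", np.arange(len(df)))
    df.insert(1, "channel", channel)
    df["params_json"] = df.get("params_json", "{}")
    return df[cols].sort_values("onset_s").reset_index(drop=True)


def _smooth(x: np.ndarray, fs: float, win_s: float) -> np.ndarray:
    """Boxcar smoothing for event-shape measurements.

    A window much shorter than the event base leaves the waveform intact
    while suppressing the sample noise that would otherwise fragment
    threshold-walked base extents.
    """
    w = max(1, int(round(win_s * fs)))
    if w == 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="same")


def _base_extent(x: np.ndarray, peak: int, base_level: float) -> tuple[int, int]:
    """Half-open sample extent of the event base around ``peak``.

    Walk outwards from the peak to where |x| stays below ``base_level``.
    """
    absx = np.abs(x)
    lo = peak
    while lo > 0 and absx[lo - 1] > base_level:
        lo -= 1
    hi = peak
    while hi < x.size - 1 and absx[hi + 1] > base_level:
        hi += 1
    return lo, hi + 1


def _incidence_gate(
    df: pd.DataFrame, duration: float, t0: float, seg_s: float, lo: float, hi: float
) -> pd.DataFrame:
    """Keep events only in segments whose incidence falls inside [lo, hi]."""
    if df.empty:
        return df
    keep = np.zeros(len(df), dtype=bool)
    n_seg = max(1, int(np.ceil(duration / seg_s)))
    for s in range(n_seg):
        a = t0 + s * seg_s
        b = min(t0 + duration, a + seg_s)
        in_seg = (df["onset_s"] >= a) & (df["onset_s"] < b)
        rate = in_seg.sum() / (b - a)
        if lo <= rate <= hi:
            keep |= in_seg.to_numpy()
    return df[keep].reset_index(drop=True)


def detect_spw(
    trace: Trace,
    amplitude_factor: float = 2.0,
    base_duration_ms: tuple[float, float] = (20.0, 200.0),
    incidence_per_s: tuple[float, float] = (0.3, 4.0),
    segment_s: float = 60.0,
) -> pd.DataFrame:
    """Detect in-vitro sharp waves (SPWs) on a slice field-potential trace.

    Events must satisfy all three criteria: amplitude about
    ``amplitude_factor`` x background, base duration 20-200 ms, and an
    incidence of 0.3-4 events/s computed over 1-min data segments.
    """
    if trace.duration < segment_s:
        warnings.warn(
            f"trace shorter than {segment_s:g} s; incidence computed over the "
            "full length",
            stacklevel=2,
        )
    x = trace.samples
    bg = _mad_sd(x)
    if bg == 0:
        return _event_table([], trace.channel)
    xs = _smooth(x, trace.fs, 0.010)  # << 20 ms minimum base duration
    peaks, props = sps.find_peaks(
        np.abs(xs), height=amplitude_factor * bg, distance=max(1, int(0.02 * trace.fs))
    )
    rows = []
    last_hi = -1
    for pk, amp in zip(peaks, props["peak_heights"]):
        lo, hi = _base_extent(xs, pk, bg)
        if lo < last_hi:  # same event as the previous peak
            continue
        last_hi = hi
        base_ms = (hi - lo) / trace.fs * 1e3
        if not (base_duration_ms[0] <= base_ms <= base_duration_ms[1]):
            continue
        rows.append(
            dict(
                kind="SPW",
                onset_s=trace.t0 + lo / trace.fs,
                termination_s=trace.t0 + hi / trace.fs,
                peak_amplitude=float(amp),
                base_duration_s=base_ms / 1e3,
            )
        )
    df = _event_table(rows, trace.channel)
    return _incidence_gate(
        df, trace.duration, trace.t0, segment_s, incidence_per_s[0], incidence_per_s[1]
    )


def detect_interictal(
    trace: Trace,
    amplitude_mv: float = 0.5,
    base_duration_s: tuple[float, float] = (0.2, 0.6),
    incidence_per_10s: tuple[float, float] = (2.0, 5.0),
    prefilter: bool = True,
) -> pd.DataFrame:
    """Detect interictal spikes by threshold search (absolute 0.5 mV rule).

    Requires ``trace.units == 'mV'``.  The trace is optionally pre-treated
    with the 0.2-500 Hz zero-phase Bessel band-pass before the threshold
    search.
    """
    if trace.units != "mV":
        raise UnitError(
            f"interictal detection uses an absolute {amplitude_mv} mV threshold; "
            f"trace units are {trace.units!r}, expected 'mV'"
        )
    work = trace
    if prefilter:
        work = bandpass_bessel(trace, 0.2, min(500.0, 0.45 * trace.fs))
    x = work.samples
    bg = _mad_sd(x)
    xs = _smooth(x, trace.fs, 0.020)  # << 200 ms minimum base duration
    peaks, props = sps.find_peaks(
        np.abs(xs), height=amplitude_mv, distance=max(1, int(0.1 * trace.fs))
    )
    rows = []
    last_hi = -1
    for pk, amp in zip(peaks, props["peak_heights"]):
        lo, hi = _base_extent(xs, pk, max(2.0 * bg, 0.1 * amp))
        if lo < last_hi:
            continue
        last_hi = hi
        base = (hi - lo) / trace.fs
        if not (base_duration_s[0] <= base <= base_duration_s[1]):
            continue
        rows.append(
            dict(
                kind="INTERICTAL",
                onset_s=trace.t0 + lo / trace.fs,
                termination_s=trace.t0 + hi / trace.fs,
                peak_amplitude=float(amp),
                base_duration_s=base,
            )
        )
    df = _event_table(rows, trace.channel)
    return _incidence_gate(
        df,
        trace.duration,
        trace.t0,
        10.0,
        incidence_per_10s[0] / 10.0,
        incidence_per_10s[1] / 10.0,
    )


@dataclass
class IctalDetection:
    """Ictal-discharge events plus the trace-level classification."""

    events: pd.DataFrame
    is_ictal: bool
    mean_duration_s: float
    mean_interevent_s: float


def detect_ictal_invitro(
    trace: Trace,
    amplitude_mv: float = 1.0,
    min_mean_duration_s: float = 30.0,
    min_mean_interevent_s: float = 90.0,
    merge_gap_s: float = 5.0,
) -> IctalDetection:
    """Detect in-vitro ictal discharges (>= 1 mV bursts) and classify the trace.

    The trace is ictal-bearing only when events exist with mean duration
    >= 30 s and mean interevent interval >= 90 s (vacuously satisfied for a
    single event).
    """
    if trace.units != "mV":
        raise UnitError(
            f"ictal detection uses an absolute {amplitude_mv} mV threshold; "
            f"trace units are {trace.units!r}, expected 'mV'"
        )
    x = trace.samples
    bg = _mad_sd(x)
    xs = _smooth(x, trace.fs, 0.020)
    above = np.flatnonzero(np.abs(x) >= amplitude_mv)
    rows = []
    if above.size:
        gaps = np.diff(above) > merge_gap_s * trace.fs
        starts = np.concatenate([[0], np.flatnonzero(gaps) + 1])
        stops = np.concatenate([np.flatnonzero(gaps), [above.size - 1]])
        for a, b in zip(starts, stops):
            lo, _ = _base_extent(xs, above[a], 2.0 * bg)
            _, hi = _base_extent(xs, above[b], 2.0 * bg)
            seg = np.abs(x[lo:hi])
            rows.append(
                dict(
                    kind="ICTAL",
                    onset_s=trace.t0 + lo / trace.fs,
                    termination_s=trace.t0 + hi / trace.fs,
                    peak_amplitude=float(seg.max()),
                    base_duration_s=(hi - lo) / trace.fs,
                )
            )
    df = _event_table(rows, trace.channel)
    if df.empty:
        return IctalDetection(df, False, float("nan"), float("nan"))
    durations = (df["termination_s"] - df["onset_s"]).to_numpy()
    mean_dur = float(durations.mean())
    if len(df) >= 2:
        iei = float(np.diff(df["onset_s"].to_numpy()).mean())
    else:
        iei = float("inf")
    is_ictal = mean_dur >= min_mean_duration_s and iei >= min_mean_interevent_s
    return IctalDetection(df, bool(is_ictal), mean_dur, iei)


# ---------------------------------------------------------------------------
# Peri-ictal epoch segmentation
# ---------------------------------------------------------------------------

EPOCH_S = 8.0


@dataclass
class EpochSegmentation:
    """Five half-open peri-ictal intervals around one discharge.

    preictal [onset-8, onset), onset [onset, onset+8),
    ictal [onset+8, term-8), offset [term-8, term), postictal [term, term+8);
    intervals are truncated at the trace boundaries (flagged), and the
    middle ictal interval is None (flagged) when the event is <= 16 s.
    """

    intervals: dict[str, tuple[float, float] | None]
    truncated: dict[str, bool]
    middle_empty: bool


def segment_epochs(
    event: DischargeEvent, trace_extent: tuple[float, float]
) -> EpochSegmentation:
    """Partition [onset-8, termination+8) into the five peri-ictal epochs."""
    t_lo, t_hi = trace_extent
    on, term = event.onset_s, event.termination_s
    if term <= on:
        raise InvalidArgumentError("event has non-positive duration")
    raw = {
        "preictal": (on - EPOCH_S, on),
        "onset": (on, on + EPOCH_S),
        "ictal": (on + EPOCH_S, term - EPOCH_S),
        "offset": (term - EPOCH_S, term),
        "postictal": (term, term + EPOCH_S),
    }
    intervals: dict[str, tuple[float, float] | None] = {}
    truncated: dict[str, bool] = {}
    for name, (a, b) in raw.items():
        a_c, b_c = max(a, t_lo), min(b, t_hi)
        if b_c <= a_c:
            intervals[name] = None
            truncated[name] = True
        else:
            intervals[name] = (a_c, b_c)
            truncated[name] = (a_c != a) or (b_c != b)
    middle_empty = intervals["ictal"] is None
    return EpochSegmentation(intervals, truncated, middle_empty)


def discharge_events_to_frame(events: list[DischargeEvent]) -> pd.DataFrame:
    """Flatten DischargeEvents to the canonical event-table layout."""
    rows = []
    for i, ev in enumerate(events):
        params = {"onset_class": ev.onset_class}
        if ev.lvf_metrics is not None:
            params["normalized_sd_pct"] = round(ev.lvf_metrics.normalized_sd_pct, 3)
            params["lvf_length_s"] = ev.lvf_metrics.lvf_length_s
        if ev.motor_stage is not None:
            params["motor_stage"] = ev.motor_stage
        rows.append(
            dict(
                event_id=i,
                channel=ev.channel,
                kind="DISCHARGE",
                onset_s=ev.onset_s,
                termination_s=ev.termination_s,
                params_json=json.dumps(params),
            )
        )
    cols = ["event_id", "channel", "kind", "onset_s", "termination_s", "params_json"]
    return pd.DataFrame(rows, columns=cols)
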