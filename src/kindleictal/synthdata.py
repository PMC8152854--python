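"""Synthetic traces with ground truth for every downstream stage.

The generator emulates the statistical structure the analysis assumes:

* LFP-like background: Gaussian noise spectrally shaped to 1/f^alpha
  (default alpha = 1, flattened below 0.5 Hz), scaled to an exact sample SD.
* Spontaneous discharges >= 10 s built from biphasic spike trains riding on
  the background, with LVF (background attenuated to a stated fraction for
  0.5-5 s before spiking), HYP (an immediate cluster of large spikes) or
  INCREMENTAL (rate and amplitude ramping from baseline) onsets, and a
  post-discharge suppression component.
* Phase-amplitude-coupled signals: a slow oscillation at f_phase plus a
  fast carrier at f_amp whose envelope is (1-depth) + depth*(1+cos phi)/2.
* Phase-locked channel pairs sharing a narrow-band component.
* Slice field potentials (mV): sharp waves, interictal spikes and ictal
  bursts with the amplitude/duration/incidence statistics the detectors
  gate on, including deliberately sub-threshold plants for negative tests.
* Movement-artifact transients for exercising PAC window exclusion.

Every generator is a pure function of its configuration and seed.  Spike
trains are rhythmic with +/-25 % interval jitter around the requested rate
profile rather than Poisson: planted trains must never contain gaps longer
than the detector's spike-gap tolerance, which a Poisson train at onset
rates occasionally produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import AliasingError, ConflictError, InvalidArgumentError
from .events import HYP, INCREMENTAL, LVF, DischargeEvent, LVFMetrics
from .signal_io import Trace

__all__ = [
    "SynthConfig",
    "DischargeSpec",
    "CouplingSpec",
    "SliceEventSpec",
    "generate_background",
    "inject_discharge",
    "generate_discharge_recording",
    "generate_pac_signal",
    "generate_coherent_pair",
    "generate_slice_trace",
    "inject_artifact",
    "biphasic_spike",
]

SPECTRAL_FLOOR_HZ = 0.5  # 1/f shaping flattens below this frequency


@dataclass(frozen=True)
class SynthConfig:
    """Acquisition-level configuration for synthetic traces."""

    duration: float  # seconds
    fs: float = 5000.0  # Hz, matching the recording digitization rate
    seed: int = 0
    background_sd: float = 1.0  # volts (mV for slice traces)
    spectral_exponent: float = 1.0  # 1/f^alpha background shaping

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidArgumentError("duration must be positive")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.background_sd < 0:
            raise InvalidArgumentError("background_sd must be nonnegative")


@dataclass(frozen=True)
class DischargeSpec:
    """One discharge to plant: onset class, timing and spike statistics."""

    onset_time: float
    total_duration: float = 30.0  # s; the recognition rule requires >= 10
    onset_class: str = LVF
    lvf_attenuation: float = 0.4  # fraction of preceding amplitude (<= 0.65)
    lvf_length: float = 2.0  # s, in [0.5, 5]
    spike_rate_profile: float = 8.0  # events/s (scalar or callable of t)
    spike_amplitude: float = 5.0  # multiples of background SD (>= 2)
    suppression_length: float = 3.0  # s
    spike_width_s: float = 0.04

    def __post_init__(self) -> None:
        if self.total_duration < 10.0:
            raise InvalidArgumentError(
                "total_duration must be >= 10 s (the recognition rule)"
            )
        if self.onset_class == LVF and not (0.5 <= self.lvf_length <= 5.0):
            raise InvalidArgumentError("lvf_length must be in [0.5, 5] s")
        if self.spike_amplitude < 2.0:
            raise InvalidArgumentError("spike_amplitude must be >= 2 background SDs")

    def rate_at(self, t_rel: float) -> float:
        if callable(self.spike_rate_profile):
            return float(self.spike_rate_profile(t_rel))
        return float(self.spike_rate_profile)


@dataclass(frozen=True)
class CouplingSpec:
    """Planted phase-amplitude coupling between one frequency pair."""

    f_phase: float = 8.0  # Hz, slow (phase-providing) oscillation
    f_amp: float = 80.0  # Hz, fast (amplitude-providing) carrier
    depth: float = 1.0  # modulation depth in [0, 1]
    carrier_amplitude: float = 3.0  # volts; 3x the default background SD

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth <= 1.0):
            raise InvalidArgumentError("depth must be in [0, 1]")
        if not (0 < self.f_phase < self.f_amp):
            raise InvalidArgumentError("need 0 < f_phase < f_amp")


@dataclass(frozen=True)
class SliceEventSpec:
    """A train of slice field-potential events to plant."""

    kind: str  # "SPW" | "INTERICTAL" | "ICTAL"
    amplitude: float  # mV
    base_duration: float  # s
    rate: float | None = None  # events/s (SPW, INTERICTAL)
    interevent_interval: float | None = None  # s (ICTAL)

    def __post_init__(self) -> None:
        if self.kind not in ("SPW", "INTERICTAL", "ICTAL"):
            raise InvalidArgumentError(f"unknown slice event kind {self.kind!r}")
        if self.kind == "ICTAL" and self.interevent_interval is None:
            raise InvalidArgumentError("ICTAL events need interevent_interval")
        if self.kind != "ICTAL" and self.rate is None:
            raise InvalidArgumentError(f"{self.kind} events need a rate")


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------


def generate_background(config: SynthConfig, channel: str = "ch0", units: str = "V") -> Trace:
    """Zero-mean 1/f^alpha Gaussian background with exact sample SD.

    White Gaussian noise is shaped in the frequency domain by
    f^(-alpha/2) (power 1/f^alpha), flattened below ``SPECTRAL_FLOOR_HZ``,
    then rescaled so the sample SD equals ``background_sd`` exactly.
    Bit-identical under identical (config, seed).
    """
    n = int(round(config.duration * config.fs))
    if n < 2:
        raise InvalidArgumentError("duration too short for the sampling rate")
    rng = np.random.default_rng(config.seed)
    white = rng.standard_normal(n)
    if config.background_sd == 0:
        return Trace(np.zeros(n), config.fs, channel, units)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / config.fs)
    shaping = np.maximum(f, SPECTRAL_FLOOR_HZ) ** (-config.spectral_exponent / 2.0)
    shaping[0] = 0.0  # remove DC
    x = np.fft.irfft(spec * shaping, n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x *= config.background_sd / sd
    return Trace(x, config.fs, channel, units)


# ---------------------------------------------------------------------------
# Spike template and trains
# ---------------------------------------------------------------------------


def biphasic_spike(width_s: float, fs: float) -> np.ndarray:
    """Biphasic spike template (difference of Gaussians), peak |value| = 1."""
    n = max(3, int(round(width_s * fs)))
    t = (np.arange(n) - n / 2) / fs
    sigma = width_s / 6.0
    w = np.exp(-((t + width_s / 8) ** 2) / (2 * sigma**2)) - 0.7 * np.exp(
        -((t - width_s / 8) ** 2) / (2 * sigma**2)
    )
    return w / np.max(np.abs(w))


def _rhythmic_times(
    rng: np.random.Generator,
    t_start: float,
    t_stop: float,
    rate_fn,
    jitter: float = 0.25,
) -> np.ndarray:
    """Jittered-rhythmic event times following a (possibly varying) rate."""
    times = []
    t = t_start
    while t < t_stop:
        rate = max(rate_fn(t - t_start), 1e-6)
        times.append(t)
        t += (1.0 / rate) * rng.uniform(1.0 - jitter, 1.0 + jitter)
    return np.asarray(times)


def _add_template(x: np.ndarray, fs: float, t0: float, t: float, template: np.ndarray, amp: float) -> None:
    i = int(round((t - t0) * fs)) - template.size // 2
    lo, hi = max(i, 0), min(i + template.size, x.size)
    if hi > lo:
        x[lo:hi] += amp * template[lo - i : hi - i]


# ---------------------------------------------------------------------------
# In-vivo discharges
# ---------------------------------------------------------------------------


def inject_discharge(
    trace: Trace,
    spec: DischargeSpec,
    seed: int = 0,
    existing: list[DischargeEvent] | None = None,
) -> tuple[Trace, DischargeEvent]:
    """Plant one discharge into ``trace``; returns (new trace, ground truth).

    The input trace is not modified.  Raises :class:`ConflictError` when the
    discharge (including its suppression tail) overlaps an event in
    ``existing``.
    """
    on = spec.onset_time
    term = on + spec.total_duration
    t_end_needed = term + spec.suppression_length
    if on < trace.t0 or t_end_needed > trace.t_end:
        raise InvalidArgumentError(
            f"discharge [{on:g}, {t_end_needed:g}] s does not fit inside the trace"
        )
    for ev in existing or []:
        sup = float(ev.attrs.get("suppression_length", 0.0))
        if on < ev.termination_s + sup and term + spec.suppression_length > ev.onset_s:
            raise ConflictError(
                f"discharge at {on:g} s overlaps existing event at {ev.onset_s:g} s"
            )

    rng = np.random.default_rng(seed)
    fs = trace.fs
    x = trace.samples.copy()
    sd0 = 1.4826 * np.median(np.abs(x - np.median(x)))
    if sd0 == 0:
        sd0 = x.std() or 1.0

    def idx(t: float) -> int:
        return int(round((t - trace.t0) * fs))

    template = biphasic_spike(spec.spike_width_s, fs)
    full_amp = spec.spike_amplitude * sd0

    if spec.onset_class == LVF:
        # abrupt attenuation of the running background, then incremental
        # rhythmic spikes ramping into the sustained train
        x[idx(on) : idx(on + spec.lvf_length)] *= spec.lvf_attenuation
        t_sp0 = on + spec.lvf_length
        ramp_s = min(2.0, 0.2 * (term - t_sp0))

        def rate(tr: float) -> float:
            base = spec.rate_at(tr)
            return base * (0.5 + 0.5 * min(tr / ramp_s, 1.0)) if ramp_s > 0 else base

        def amp(tr: float) -> float:
            return full_amp * (0.5 + 0.5 * min(tr / ramp_s, 1.0)) if ramp_s > 0 else full_amp

    elif spec.onset_class == HYP:
        # a cluster of abruptly arising large spikes from the baseline
        t_sp0 = on
        for k in range(4):
            _add_template(
                x, fs, trace.t0, on + 0.05 + 0.22 * k, template,
                full_amp * rng.uniform(0.9, 1.1),
            )

        def rate(tr: float) -> float:
            return spec.rate_at(tr)

        def amp(tr: float) -> float:
            return full_amp

        t_sp0 = on + 1.0
    elif spec.onset_class == INCREMENTAL:
        t_sp0 = on
        ramp_s = max(1.0, 0.4 * spec.total_duration)

        def rate(tr: float) -> float:
            return 2.0 + (spec.rate_at(tr) - 2.0) * min(tr / ramp_s, 1.0)

        def amp(tr: float) -> float:
            return sd0 * (
                1.5 + (spec.spike_amplitude - 1.5) * min(tr / ramp_s, 1.0)
            )

    else:
        raise InvalidArgumentError(f"unknown onset class {spec.onset_class!r}")

    for t in _rhythmic_times(rng, t_sp0, term - 0.05, rate):
        _add_template(x, fs, trace.t0, t, template, amp(t - t_sp0) * rng.uniform(0.85, 1.15))

    # post-discharge suppression
    x[idx(term) : idx(term + spec.suppression_length)] *= 0.3

    metrics = None
    if spec.onset_class == LVF:
        metrics = LVFMetrics(
            lvf_start_s=on,
            lvf_length_s=spec.lvf_length,
            sd_lvf=spec.lvf_attenuation * sd0,
            sd_preceding=sd0,
        )
    truth = DischargeEvent(
        channel=trace.channel,
        onset_s=on,
        termination_s=term,
        onset_class=spec.onset_class,
        lvf_metrics=metrics,
        attrs={
            "planted": True,
            "planted_attenuation": spec.lvf_attenuation if spec.onset_class == LVF else None,
            "suppression_length": spec.suppression_length,
            "background_sd": float(sd0),
        },
    )
    return replace(trace, samples=x), truth


def generate_discharge_recording(
    config: SynthConfig,
    specs: list[DischargeSpec],
    channel: str = "ch0",
) -> tuple[Trace, list[DischargeEvent]]:
    """Background plus a sequence of planted discharges with ground truth."""
    trace = generate_background(config, channel=channel)
    truths: list[DischargeEvent] = []
    for k, spec in enumerate(sorted(specs, key=lambda s: s.onset_time)):
        trace, truth = inject_discharge(
            trace, spec, seed=config.seed + 1000 + k, existing=truths
        )
        truths.append(truth)
    return trace, truths


# ---------------------------------------------------------------------------
# Coupled and coherent signals
# ---------------------------------------------------------------------------


def generate_pac_signal(
    coupling: CouplingSpec, config: SynthConfig, channel: str = "ch0"
) -> tuple[Trace, CouplingSpec]:
    """Slow oscillation + phase-modulated fast carrier + background.

    The carrier envelope is (1 - depth) + depth * (1 + cos phi_low)/2, so
    depth = 0 leaves the envelope constant and depth = 1 makes it vanish at
    the anti-preferred phase.  Returns the trace and its ground truth.
    """
    if coupling.f_amp >= config.fs / 2:
        raise AliasingError(
            f"f_amp {coupling.f_amp} Hz >= Nyquist {config.fs / 2} Hz"
        )
    bg = generate_background(config, channel=channel)
    t = bg.times()
    phi = 2 * np.pi * coupling.f_phase * t
    slow = np.cos(phi)
    envelope = (1.0 - coupling.depth) + coupling.depth * (1.0 + np.cos(phi)) / 2.0
    fast = envelope * np.cos(2 * np.pi * coupling.f_amp * t)
    samples = bg.samples + coupling.carrier_amplitude * (slow + fast)
    return replace(bg, samples=samples), coupling


def generate_coherent_pair(
    band_center: float,
    lock_fraction: float,
    config: SynthConfig,
    phase_lag: float = 0.0,
    gain: float = 1.0,
    channels: tuple[str, str] = ("ch0", "ch1"),
) -> tuple[Trace, Trace]:
    """Two traces sharing a narrow-band component scaled by ``lock_fraction``.

    Each trace is lock_fraction * shared + (1 - lock_fraction) * independent
    noise; at lock_fraction = 1 the traces differ only by the constant
    ``gain`` and ``phase_lag`` (radians at ``band_center``).
    """
    if band_center >= config.fs / 2:
        raise AliasingError(f"band_center {band_center} Hz >= Nyquist {config.fs / 2} Hz")
    if not (0.0 <= lock_fraction <= 1.0):
        raise InvalidArgumentError("lock_fraction must be in [0, 1]")
    n = int(round(config.duration * config.fs))
    rng = np.random.default_rng(config.seed)
    lo, hi = band_center / 2**0.25, band_center * 2**0.25
    sos = sps.butter(4, [lo, min(hi, 0.49 * config.fs)], "bandpass", fs=config.fs, output="sos")
    shared = sps.sosfilt(sos, rng.standard_normal(n))
    shared /= shared.std() or 1.0
    shared *= config.background_sd
    shift = int(round(phase_lag / (2 * np.pi * band_center) * config.fs))
    shared_b = gain * np.roll(shared, shift)
    noise_sd = (1.0 - lock_fraction) * config.background_sd
    n1 = rng.standard_normal(n) * noise_sd
    n2 = rng.standard_normal(n) * noise_sd
    a = Trace(lock_fraction * shared + n1, config.fs, channels[0])
    b = Trace(lock_fraction * shared_b + n2, config.fs, channels[1])
    return a, b


# ---------------------------------------------------------------------------
# Slice field potentials
# ---------------------------------------------------------------------------


def _gaussian_event(fs: float, amplitude: float, base_s: float, base_level: float) -> np.ndarray:
    """Gaussian field event sized so |x| crosses ``base_level`` at ``base_s``.

    sigma solves A*exp(-(base/2)^2 / (2 sigma^2)) = base_level, so a
    threshold-walking detector recovers the planted base duration.
    """
    ratio = max(amplitude / max(base_level, 1e-12), 1.0 + 1e-6)
    sigma = (base_s / 2.0) / np.sqrt(2.0 * np.log(ratio))
    half = int(round(3.0 * sigma * fs)) + 1
    t = np.arange(-half, half + 1) / fs
    return amplitude * np.exp(-(t**2) / (2 * sigma**2))


def _ictal_burst(fs: float, amplitude: float, duration_s: float, rng) -> np.ndarray:
    n = int(round(duration_s * fs))
    env = sps.windows.tukey(n, alpha=0.15)
    osc = np.sin(2 * np.pi * 6.0 * np.arange(n) / fs + rng.uniform(0, 2 * np.pi))
    return amplitude * env * osc


def generate_slice_trace(
    specs: list[SliceEventSpec],
    config: SynthConfig,
    channel: str = "slice0",
) -> tuple[Trace, pd.DataFrame]:
    """Slice field-potential trace (mV) with a ground-truth event table.

    Events are placed on jittered-rhythmic grids; later plants are shifted
    off occupied intervals (or dropped) so planted events never overlap.
    Overlapping ictal bursts raise :class:`ConflictError`.  The returned
    table flags each event with ``meets_criteria``: whether its amplitude,
    base duration and train incidence satisfy the corresponding detection
    rule (sub-threshold plants are the detectors' negative controls).
    """
    trace = generate_background(config, channel=channel, units="mV")
    rng = np.random.default_rng(config.seed + 7)
    x = trace.samples
    fs = config.fs
    bg = config.background_sd
    occupied: list[tuple[float, float]] = []
    rows: list[dict] = []

    def overlaps(a: float, b: float) -> bool:
        return any(a < hi + 0.05 and b > lo - 0.05 for lo, hi in occupied)

    # plant ictal bursts first (largest footprint)
    for spec in [s for s in specs if s.kind == "ICTAL"]:
        iei = float(spec.interevent_interval)
        t = iei * 0.5
        while t + spec.base_duration < config.duration:
            a, b = t, t + spec.base_duration
            if overlaps(a, b):
                raise ConflictError(f"ictal event at {t:g} s overlaps an existing event")
            burst = _ictal_burst(fs, spec.amplitude, spec.base_duration, rng)
            i0 = int(round(a * fs))
            x[i0 : i0 + burst.size] += burst[: max(0, x.size - i0)]
            occupied.append((a, b))
            rows.append(_slice_row(spec, a, b, bg))
            t += iei

    for spec in [s for s in specs if s.kind != "ICTAL"]:
        interval = 1.0 / float(spec.rate)
        base_level = (
            max(2.0 * bg, 0.1 * spec.amplitude) if spec.kind == "INTERICTAL" else bg
        )
        shape = _gaussian_event(fs, spec.amplitude, spec.base_duration, base_level)
        sign = -1.0 if spec.kind == "SPW" else 1.0
        unit_shape = shape / np.max(np.abs(shape))
        t = interval * rng.uniform(0.3, 0.7)
        while t + spec.base_duration / 2 < config.duration:
            a = t - spec.base_duration / 2
            b = t + spec.base_duration / 2
            for shift in np.arange(0.0, interval * 0.8, max(0.05, spec.base_duration)):
                if a + shift >= 0 and not overlaps(a + shift, b + shift):
                    _add_template(
                        x, fs, trace.t0, t + shift, unit_shape, sign * spec.amplitude
                    )
                    occupied.append((a + shift, b + shift))
                    rows.append(_slice_row(spec, a + shift, b + shift, bg))
                    break
            t += interval * rng.uniform(0.85, 1.15)

    truth = pd.DataFrame(
        rows,
        columns=[
            "kind",
            "onset_s",
            "termination_s",
            "peak_amplitude",
            "base_duration_s",
            "meets_criteria",
            "params_json",
        ],
    ).sort_values("onset_s").reset_index(drop=True)
    truth.insert(0, "event_id", np.arange(len(truth)))
    truth.insert(1, "channel", channel)
    return replace(trace, samples=x), truth


def _slice_row(spec: SliceEventSpec, a: float, b: float, bg: float) -> dict:
    base = b - a
    if spec.kind == "SPW":
        ok = spec.amplitude >= 2.0 * bg and 0.02 <= base <= 0.2 and spec.rate is not None and 0.3 <= spec.rate <= 4.0
    elif spec.kind == "INTERICTAL":
        ok = spec.amplitude >= 0.5 and 0.2 <= base <= 0.6 and spec.rate is not None and 0.2 <= spec.rate <= 0.5
    else:
        ok = spec.amplitude >= 1.0
    return dict(
        kind=spec.kind,
        onset_s=a,
        termination_s=b,
        peak_amplitude=spec.amplitude,
        base_duration_s=base,
        meets_criteria=bool(ok),
        params_json=json.dumps({"rate": spec.rate, "iei": spec.interevent_interval}),
    )


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------


def inject_artifact(
    trace: Trace,
    times: list[float],
    magnitude: float = 10.0,
    width: float = 0.2,
) -> tuple[Trace, list[float]]:
    """Add large movement-artifact transients; returns (trace, times).

    Each artifact is a Gaussian transient of peak ``magnitude`` x the
    trace's robust background SD and total width ~``width`` seconds.
    An empty ``times`` list returns the trace unchanged.
    """
    x = trace.samples.copy()
    if not times:
        return replace(trace, samples=x), []
    for t in times:
        if not (trace.t0 <= t <= trace.t_end):
            raise InvalidArgumentError(f"artifact time {t:g} s outside the trace")
    sd0 = 1.4826 * np.median(np.abs(x - np.median(x)))
    if sd0 == 0:
        sd0 = x.std() or 1.0
    sigma = width / 4.0
    half = int(round(3 * sigma * trace.fs)) + 1
    tt = np.arange(-half, half + 1) / trace.fs
    bump = np.exp(-(tt**2) / (2 * sigma**2))
    for t in times:
        _add_template(x, trace.fs, trace.t0, t, bump, magnitude * sd0)
    return replace(trace, samples=x), list(times)
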