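"""Trace and event-table I/O plus fixed filtering operations.

The central container is :class:`Trace`, a uniformly sampled single-channel
voltage series.  Filters mirror the analog-style instrumentation chain used
for intracranial EEG and slice field potentials: an 8-pole Bessel band-pass
(applied forward-backward for zero phase), a 60 +/- 3 Hz notch, and an
anti-aliased downsampler.

CSV dialect: header lines ``fs=<Hz>``, ``units=<str>``, ``channel=<str>``,
optionally ``t0=<s>``, followed by one sample per line.  EDF writing uses a
minimal single-channel EDF encoder (16-bit); reading goes through ``mne``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .errors import AliasingError, InvalidArgumentError, ParseError

__all__ = [
    "Trace",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "bandpass_bessel",
    "notch",
    "downsample",
]

EVENT_COLUMNS = ["event_id", "channel", "kind", "onset_s", "termination_s", "params_json"]


@dataclass
class Trace:
    """Uniformly sampled voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage samples (1-D, float64).
    fs : float
        Sampling rate in Hz.
    channel : str
        Channel label.
    units : str
        Physical units of the samples ("V" or "mV").
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel: str = "ch0"
    units: str = "V"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_of(self, t: float) -> int:
        """Sample index of time ``t`` (clipped to the valid range)."""
        return int(np.clip(round((t - self.t0) * self.fs), 0, self.n - 1))

    def slice(self, start_s: float, stop_s: float) -> "Trace":
        """Sub-trace on the half-open interval [start_s, stop_s)."""
        i0 = int(np.clip(round((start_s - self.t0) * self.fs), 0, self.n))
        i1 = int(np.clip(round((stop_s - self.t0) * self.fs), 0, self.n))
        if i1 <= i0:
            raise InvalidArgumentError("empty slice requested")
        return replace(self, samples=self.samples[i0:i1].copy(), t0=self.t0 + i0 / self.fs)

    def copy(self) -> "Trace":
        return replace(self, samples=self.samples.copy())


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------


def write_trace(trace: Trace, path, format: str | None = None) -> None:
    """Write a trace as CSV (plain-text dialect) or EDF (16-bit)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"fs={trace.fs!r}\n")
            fh.write(f"units={trace.units}\n")
            fh.write(f"channel={trace.channel}\n")
            fh.write(f"t0={trace.t0!r}\n")
            np.savetxt(fh, trace.samples, fmt="%.10g")
    elif fmt == "edf":
        _write_edf(trace, path)
    else:
        raise InvalidArgumentError(f"unknown trace format: {fmt!r}")


def read_trace(path, format: str | None = None) -> Trace:
    """Read a trace from CSV or EDF.

    Raises
    ------
    ParseError
        If a required header field is missing or malformed (the message
        names the field).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise InvalidArgumentError(f"unknown trace format: {fmt!r}")


def _read_csv(path: Path) -> Trace:
    header: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if "=" in line and not _is_number(line):
                key, _, value = line.partition("=")
                header[key.strip()] = value.strip()
            else:
                try:
                    samples.append(float(line))
                except ValueError as exc:
                    raise ParseError(f"unparseable sample line: {line!r}") from exc
    if "fs" not in header:
        raise ParseError("missing required header field 'fs'")
    try:
        fs = float(header["fs"])
    except ValueError as exc:
        raise ParseError(f"malformed header field 'fs': {header['fs']!r}") from exc
    if not samples:
        raise ParseError("no samples found in CSV trace")
    return Trace(
        samples=np.asarray(samples),
        fs=fs,
        channel=header.get("channel", "ch0"),
        units=header.get("units", "V"),
        t0=float(header.get("t0", 0.0)),
    )


def _is_number(line: str) -> bool:
    try:
        float(line)
        return True
    except ValueError:
        return False


def _write_edf(trace: Trace, path: Path) -> None:
    """Minimal single-channel EDF writer (1-s data records, zero padding).

    Traces whose length is not a whole number of seconds are zero padded to
    the next full second; readers therefore return the padded length.
    """
    fs = trace.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidArgumentError("EDF writing requires an integer sampling rate")
    fs_i = int(round(fs))
    x = trace.samples
    n_records = int(np.ceil(x.size / fs_i))
    pad = n_records * fs_i - x.size
    if pad:
        x = np.concatenate([x, np.zeros(pad)])
    phys_max = float(max(np.max(np.abs(x)), 1e-9))
    dig_max, dig_min = 32767, -32768
    digital = np.clip(np.round(x / phys_max * dig_max), dig_min, dig_max).astype("<i2")

    def f(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),  # version
            f("X X X X", 80),  # patient id
            f("Startdate X X X X", 80),  # recording id
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 + 256), 8),  # header bytes
            f("EDF", 44),  # reserved
            f(str(n_records), 8),
            f(str(1), 8),  # record duration, s
            f(str(1), 4),  # number of signals
            f(trace.channel, 16),  # label
            f("", 80),  # transducer
            f(trace.units, 8),  # physical dimension
            f(f"{-phys_max:.6g}", 8),
            f(f"{phys_max:.6g}", 8),
            f(str(dig_min), 8),
            f(str(dig_max), 8),
            f("", 80),  # prefiltering
            f(str(fs_i), 8),  # samples per record
            f("", 32),  # reserved
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def _read_edf(path: Path) -> Trace:
    import mne  # heavy import kept local

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[0]
    # mne rescales EDF voltages to SI volts using the physical dimension;
    # recover the stored unit by inspecting the header's unit string.
    units = "V"
    try:
        unit_str = raw._orig_units[raw.ch_names[0]]  # e.g. "mV"
        if unit_str:
            units = unit_str
            if unit_str == "mV":
                data = data * 1e3
            elif unit_str in ("uV", "µV"):
                data = data * 1e6
    except (AttributeError, KeyError):
        pass
    return Trace(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel=raw.ch_names[0],
        units=units,
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def write_events(table: pd.DataFrame, path) -> None:
    """Write an event table (CSV, canonical column order first)."""
    cols = [c for c in EVENT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.loc[:, cols].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("onset_s", "termination_s", "kind") if c not in table.columns]
    if missing:
        raise ParseError(f"event table missing required column(s): {missing}")
    bad = table["onset_s"] >= table["termination_s"]
    if bad.any():
        raise ParseError(
            f"event table rows with onset_s >= termination_s: {list(table.index[bad])}"
        )
    return table.sort_values("onset_s").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def _bessel_sos(low: float, high: float, order: int, fs: float) -> np.ndarray:
    """Design an ``order``-pole Bessel band-pass with pre-warped corners.

    The filter is meant to be applied forward-backward (magnitude squared),
    so the design corners are adjusted until the *combined* response is
    -3 dB at the stated corners.
    """

    def design(lo: float, hi: float) -> np.ndarray:
        return signal.bessel(order // 2, [lo, hi], "bandpass", fs=fs, output="sos", norm="mag")

    def combined_mag(sos: np.ndarray, f: float) -> float:
        _, h = signal.sosfreqz(sos, worN=[f], fs=fs)
        return float(np.abs(h[0]) ** 2)  # filtfilt squares the magnitude

    lo_d, hi_d = low, high
    target = 1.0 / np.sqrt(2.0)
    for _ in range(2):  # edges are far apart; two passes converge
        try:
            lo_d = optimize.brentq(
                lambda v: combined_mag(design(v, hi_d), low) - target, low * 0.05, low
            )
        except ValueError:
            pass
        try:
            hi_d = optimize.brentq(
                lambda v: combined_mag(design(lo_d, v), high) - target,
                high,
                min(high * 4, fs / 2 * 0.999),
            )
        except ValueError:
            pass
    return design(lo_d, hi_d)


def bandpass_bessel(trace: Trace, low: float, high: float, order: int = 8) -> Trace:
    """Zero-phase Bessel band-pass (``order`` poles total, forward-backward).

    Emulates the analog instrumentation filter used on EEG (2-200 Hz) and
    slice field potentials (0.2-500 Hz), but applied forward-backward so
    event onset times are not delayed.
    """
    if not (0 < low < high):
        raise InvalidArgumentError(f"need 0 < low < high, got ({low}, {high})")
    if high >= trace.fs / 2:
        raise AliasingError(f"high corner {high} Hz >= Nyquist {trace.fs / 2} Hz")
    if order % 2:
        raise InvalidArgumentError("order (pole count) must be even")
    sos = _bessel_sos(low, high, order, trace.fs)
    out = signal.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=out)


def notch(trace: Trace, center: float = 60.0, half_width: float = 3.0) -> Trace:
    """Zero-phase notch at ``center`` +/- ``half_width`` Hz (default 60 +/- 3)."""
    if center >= trace.fs / 2:
        raise AliasingError(f"notch center {center} Hz >= Nyquist {trace.fs / 2} Hz")
    q = center / (2.0 * half_width)
    b, a = signal.iirnotch(center, q, fs=trace.fs)
    out = signal.filtfilt(b, a, trace.samples)
    return replace(trace, samples=out)


def downsample(
    trace: Trace,
    factor: float,
    min_nyquist: float | None = None,
    on_violation: str = "warn",
) -> Trace:
    """Anti-aliased downsampling by an integer or rational ``factor``.

    Parameters
    ----------
    min_nyquist : float, optional
        If given, require new fs/2 >= ``min_nyquist`` (e.g. 512 Hz when the
        full PAC amplitude band is to be analysed afterwards); violations
        warn or raise per ``on_violation`` ("warn" | "error").
    """
    if factor < 1:
        raise InvalidArgumentError("factor must be >= 1")
    if factor == 1:
        return trace.copy()
    frac = Fraction(factor).limit_denominator(1000)
    up, down = frac.denominator, frac.numerator
    new_fs = trace.fs * up / down
    if min_nyquist is not None and new_fs / 2 < min_nyquist:
        msg = (
            f"downsampled Nyquist {new_fs / 2:g} Hz is below the requested "
            f"analysis band limit {min_nyquist:g} Hz"
        )
        if on_violation == "error":
            raise AliasingError(msg)
        warnings.warn(msg, stacklevel=2)
    out = signal.resample_poly(trace.samples, up, down)
    return replace(trace, samples=out, fs=new_fs)
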