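"""Phase-amplitude coupling and wavelet phase coherence.

PAC strength between a slow phase frequency f_L and a fast amplitude
frequency f_H is the normalized Kullback-Leibler modulation index: the
amplitude series is averaged within 18 equal phase bins (20 degrees each),
the bin means are normalized to a distribution p, and

    MI = KL(p || uniform) / log(n_bins)  in [0, 1].

MI = 0 for amplitude independent of phase; MI = 1 when all amplitude mass
concentrates in a single bin.  Comodulograms evaluate MI over a log grid of
(f_L in 1-30 Hz) x (f_H in 32-512 Hz) in non-overlapping 4-s windows, the
window length chosen so every phase band >= 1 Hz sees at least 4 cycles.

Wavelet phase coherence between two simultaneously recorded channels is
rho = |<exp(j*dphi)>| with dphi(t, f) = angle(W1*(t,f) . W2(t,f)), the
cross-spectrum phase, averaged over windows spanning 8 cycles of each
analysis frequency.  rho = 1 iff dphi is constant within the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InvalidArgumentError
from .signal_io import Trace
from .wavelet import (
    FrequencyGrid,
    MorletParams,
    WaveletSpectrum,
    cwt_morlet,
    extract_amplitude,
    extract_phase,
    make_log_grid,
)

__all__ = [
    "Comodulogram",
    "PACWindowSeries",
    "SegmentPAC",
    "CoherenceMap",
    "modulation_index",
    "pac_windows",
    "mean_pac",
    "wpc",
    "artifact_mask",
    "wpc_null_bias",
    "default_phase_grid",
    "default_amp_grid",
]

PAC_WINDOW_S = 4.0
MIN_CYCLES_PER_WINDOW = 4.0


def default_phase_grid(points_per_octave: float = 4) -> FrequencyGrid:
    """Slow-oscillation (phase) grid, 1-30 Hz, log-spaced."""
    return make_log_grid(1.0, 30.0, points_per_octave)


def default_amp_grid(points_per_octave: float = 4) -> FrequencyGrid:
    """Fast-oscillation (amplitude) grid, 32-512 Hz, log-spaced."""
    return make_log_grid(32.0, 512.0, points_per_octave)


# ---------------------------------------------------------------------------
# Modulation index
# ---------------------------------------------------------------------------


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18
) -> float:
    """Normalized KL modulation index of ``amplitude`` over binned ``phase``.

    Phases are binned into ``n_bins`` equal bins over (-pi, pi] (18 bins of
    20 degrees by default).  Empty bins contribute p_k = 0 (0*log0 := 0).
    Returns NaN with a warning if the amplitude is identically zero.
    """
    phase = np.asarray(phase, float).ravel()
    amplitude = np.asarray(amplitude, float).ravel()
    if phase.size != amplitude.size or phase.size == 0:
        raise InvalidArgumentError("phase and amplitude must be equal-length, non-empty")
    if np.any(amplitude < 0):
        raise InvalidArgumentError("amplitude must be nonnegative")
    if not np.any(amplitude > 0):
        warnings.warn("all-zero amplitude: modulation index undefined", stacklevel=2)
        return float("nan")
    idx = _phase_bin_indices(phase, n_bins)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return _mi_from_bin_means(means, n_bins)


def _phase_bin_indices(phase: np.ndarray, n_bins: int) -> np.ndarray:
    # map (-pi, pi] to [0, n_bins); phase exactly -pi folds into bin 0
    idx = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(np.intp)
    return np.clip(idx, 0, n_bins - 1)


def _mi_from_bin_means(means: np.ndarray, n_bins: int) -> float:
    total = means.sum()
    if total <= 0:
        return float("nan")
    p = means / total
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n_bins)))
    return kl / np.log(n_bins)


# ---------------------------------------------------------------------------
# PAC windows
# ---------------------------------------------------------------------------


@dataclass
class Comodulogram:
    """MI matrix over (phase frequency) x (amplitude frequency)."""

    mi: np.ndarray  # (n_phase_freqs, n_amp_freqs)
    phase_grid: FrequencyGrid
    amp_grid: FrequencyGrid

    def argmax_pair(self) -> tuple[float, float]:
        """(f_phase, f_amp) of the strongest coupling."""
        i, j = np.unravel_index(np.nanargmax(self.mi), self.mi.shape)
        return float(self.phase_grid.frequencies[i]), float(self.amp_grid.frequencies[j])

    def grid_mean(self, reliable_rows: np.ndarray | None = None) -> float:
        """Spectral mean of MI over the grid (optionally reliable rows only)."""
        m = self.mi if reliable_rows is None else self.mi[reliable_rows, :]
        return float(np.nanmean(m))


@dataclass
class PACWindowSeries:
    """Per-window comodulograms over consecutive non-overlapping windows."""

    starts: np.ndarray  # window start times, s
    comodulograms: list[Comodulogram]
    window_s: float
    excluded: np.ndarray  # bool per window (artifact)
    reliable_phase_rows: np.ndarray  # bool per phase frequency (>= 4 cycles)

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def window_means(self) -> np.ndarray:
        """Spectral mean MI per window (NaN for excluded windows)."""
        out = np.full(self.n_windows, np.nan)
        for w, com in enumerate(self.comodulograms):
            if not self.excluded[w]:
                out[w] = com.grid_mean(self.reliable_phase_rows)
        return out

    def mean_comodulogram(self) -> Comodulogram:
        """Temporal mean comodulogram over unmasked windows."""
        keep = [c.mi for c, ex in zip(self.comodulograms, self.excluded) if not ex]
        if not keep:
            raise InvalidArgumentError("all windows are artifact-masked")
        c0 = self.comodulograms[0]
        return Comodulogram(np.mean(keep, axis=0), c0.phase_grid, c0.amp_grid)


def pac_windows(
    trace: Trace,
    phase_grid: FrequencyGrid | None = None,
    amp_grid: FrequencyGrid | None = None,
    window_s: float = PAC_WINDOW_S,
    morlet_params: MorletParams = MorletParams(),
    n_bins: int = 18,
    artifact_threshold_sd: float | None = 8.0,
    min_cycles: float = MIN_CYCLES_PER_WINDOW,
) -> PACWindowSeries:
    """Comodulogram in each non-overlapping ``window_s``-second window.

    Phase rows with fewer than ``min_cycles`` cycles per window are flagged
    unreliable (and skipped by spectral averaging); windows containing
    samples beyond ``artifact_threshold_sd`` robust SDs are flagged excluded.
    """
    phase_grid = phase_grid or default_phase_grid()
    amp_grid = amp_grid or default_amp_grid()
    if amp_grid.frequencies[-1] >= trace.fs / 2:
        raise InvalidArgumentError(
            f"amplitude grid top {amp_grid.frequencies[-1]} Hz >= Nyquist {trace.fs / 2} Hz"
        )
    win = int(round(window_s * trace.fs))
    if win < 1 or trace.n < win:
        raise InvalidArgumentError("trace shorter than one PAC window")
    n_win = trace.n // win

    phase = extract_phase(cwt_morlet(trace, phase_grid, morlet_params))
    amp = extract_amplitude(cwt_morlet(trace, amp_grid, morlet_params))

    npf, naf = len(phase_grid), len(amp_grid)
    reliable = phase_grid.frequencies * window_s >= min_cycles - 1e-9

    starts = trace.t0 + np.arange(n_win) * win / trace.fs
    if artifact_threshold_sd is not None and np.isfinite(artifact_threshold_sd):
        bounds = [(s, s + window_s) for s in starts]
        excluded = artifact_mask(trace, bounds, artifact_threshold_sd)
    else:
        excluded = np.zeros(n_win, dtype=bool)

    comods: list[Comodulogram] = []
    for w in range(n_win):
        sl = slice(w * win, (w + 1) * win)
        mi = np.empty((npf, naf))
        amp_w = amp[sl]
        for i in range(npf):
            idx = _phase_bin_indices(phase[sl, i], n_bins)
            sums = np.zeros((n_bins, naf))
            np.add.at(sums, idx, amp_w)
            counts = np.bincount(idx, minlength=n_bins).astype(float)
            means = np.divide(
                sums, counts[:, None], out=np.zeros_like(sums), where=counts[:, None] > 0
            )
            for j in range(naf):
                mi[i, j] = _mi_from_bin_means(means[:, j], n_bins)
        comods.append(Comodulogram(mi, phase_grid, amp_grid))
    return PACWindowSeries(starts, comods, window_s, excluded, reliable)


# ---------------------------------------------------------------------------
# Peri-ictal averaging
# ---------------------------------------------------------------------------

SEGMENT_NAMES = ("preictal", "onset", "ictal", "offset", "postictal")


@dataclass
class SegmentPAC:
    """Mean PAC strength per peri-ictal segment (spectral + temporal mean)."""

    mean_mi: dict[str, float]  # NaN where missing
    n_windows: dict[str, int]

    def missing(self, segment: str) -> bool:
        return self.n_windows.get(segment, 0) == 0


def mean_pac(series: PACWindowSeries, segmentation) -> SegmentPAC:
    """Average PAC per peri-ictal segment.

    Spectral averaging first (grid mean per window over reliable phase
    rows), then temporal averaging over the segment's unmasked windows; a
    window belongs to the segment containing its centre.  Segments whose
    windows are all masked (or absent) are marked missing (NaN, n=0).
    """
    wm = series.window_means()
    centers = series.starts + series.window_s / 2.0
    mean_mi: dict[str, float] = {}
    n_windows: dict[str, int] = {}
    for name in SEGMENT_NAMES:
        interval = segmentation.intervals[name]
        if interval is None:
            mean_mi[name], n_windows[name] = float("nan"), 0
            continue
        a, b = interval
        sel = (centers >= a) & (centers < b) & ~np.isnan(wm)
        n = int(np.sum(sel))
        n_windows[name] = n
        mean_mi[name] = float(np.mean(wm[sel])) if n else float("nan")
    return SegmentPAC(mean_mi, n_windows)


# ---------------------------------------------------------------------------
# Wavelet phase coherence
# ---------------------------------------------------------------------------


@dataclass
class CoherenceMap:
    """Per-frequency, per-window phase coherence rho in [0, 1].

    ``rho[k]`` holds one value per non-overlapping window of 8 cycles of
    ``frequencies[k]``; ``centers[k]`` the window-centre times.  The
    ``window_phases[k]`` hold the phase difference at each window's centre
    sample, from which :meth:`band_coherence` forms the across-window
    resultant length.  Centre samples sit 8 cycles apart -- far beyond the
    wavelet decorrelation time -- so under independence these are n iid
    uniform phasors and the null expectation is sqrt(pi/(4n)); window-mean
    phasors would be slightly correlated across window boundaries and
    would not obey that law (see ``wpc_null_bias``).
    """

    frequencies: np.ndarray
    centers: list[np.ndarray]
    rho: list[np.ndarray]
    window_phases: list[np.ndarray]
    cycles_per_window: float

    def band_coherence(self, k: int) -> float:
        """Across-window resultant length at frequency index ``k``."""
        ph = self.window_phases[k]
        if ph.size == 0:
            return float("nan")
        return float(np.abs(np.mean(np.exp(1j * ph))))

    def n_windows(self, k: int) -> int:
        return self.rho[k].size

    def to_grid(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-neighbour resampling to a common time axis (for display).

        Returns (times, matrix) with matrix shape (n_times, n_frequencies);
        NaN where a frequency has no window covering the time.
        """
        t_max = max((c[-1] if c.size else 0.0) for c in self.centers)
        times = np.arange(0.0, t_max + dt, dt)
        out = np.full((times.size, self.frequencies.size), np.nan)
        for k in range(self.frequencies.size):
            if self.centers[k].size == 0:
                continue
            idx = np.clip(
                np.searchsorted(self.centers[k], times), 0, self.centers[k].size - 1
            )
            left = np.maximum(idx - 1, 0)
            pick = np.where(
                np.abs(self.centers[k][left] - times) <= np.abs(self.centers[k][idx] - times),
                left,
                idx,
            )
            out[:, k] = self.rho[k][pick]
        return times, out


def wpc_null_bias(n_windows: int) -> float:
    """Expected resultant length of ``n_windows`` iid uniform phasors.

    sqrt(pi / (4 n)): the small-sample bias of |mean unit phasor| under
    independence, i.e. the coherence floor for unrelated signals.
    """
    if n_windows < 1:
        raise InvalidArgumentError("need at least one window")
    return float(np.sqrt(np.pi / (4.0 * n_windows)))


def wpc(
    trace_a: Trace,
    trace_b: Trace,
    grid: FrequencyGrid | None = None,
    cycles: float = 8.0,
    morlet_params: MorletParams = MorletParams(),
) -> CoherenceMap:
    """Wavelet phase coherence between two aligned channels.

    For each analysis frequency f, the phase difference
    dphi(t) = angle(W1*(t,f) W2(t,f)) is reduced over non-overlapping
    windows of ``cycles``/f seconds to rho = |<exp(j dphi)>| in [0, 1];
    rho = 1 iff dphi is constant within the window (phase lock).
    """
    if trace_a.fs != trace_b.fs:
        raise AlignmentError("traces have different sampling rates")
    if trace_a.n != trace_b.n or abs(trace_a.t0 - trace_b.t0) > 0.5 / trace_a.fs:
        raise AlignmentError("traces are not time-aligned")
    grid = grid or make_log_grid(0.25, min(512.0, trace_a.fs / 2 * 0.99), 4)
    if grid.frequencies[-1] >= trace_a.fs / 2:
        raise InvalidArgumentError("grid exceeds Nyquist")
    w1 = cwt_morlet(trace_a, grid, morlet_params).coefficients
    w2 = cwt_morlet(trace_b, grid, morlet_params).coefficients
    cross = np.conj(w1) * w2
    mag = np.abs(cross)
    phasor = np.where(mag > 0, cross / np.where(mag > 0, mag, 1.0), 1.0 + 0j)

    centers: list[np.ndarray] = []
    rhos: list[np.ndarray] = []
    wphases: list[np.ndarray] = []
    n = trace_a.n
    for k, f in enumerate(grid.frequencies):
        win = max(1, int(round(cycles / f * trace_a.fs)))
        n_win = n // win
        if n_win == 0:
            centers.append(np.empty(0))
            rhos.append(np.empty(0))
            wphases.append(np.empty(0))
            continue
        z = phasor[: n_win * win, k].reshape(n_win, win)
        mean_z = z.mean(axis=1)
        rhos.append(np.abs(mean_z))
        wphases.append(np.angle(z[:, win // 2]))
        centers.append(trace_a.t0 + (np.arange(n_win) + 0.5) * win / trace_a.fs)
    return CoherenceMap(grid.frequencies.copy(), centers, rhos, wphases, cycles)


# ---------------------------------------------------------------------------
# Artifact masking
# ---------------------------------------------------------------------------


def artifact_mask(
    trace: Trace,
    windows: list[tuple[float, float]],
    threshold_sd: float = 8.0,
) -> np.ndarray:
    """Boolean mask per window; True where the window contains samples
    exceeding ``threshold_sd`` robust (MAD-scaled) SDs from the median.

    Large movement artifacts invalidate PAC estimates, so flagged windows
    are excluded from averaging.  ``threshold_sd=inf`` masks nothing.
    """
    x = trace.samples
    med = np.median(x)
    mad_sd = 1.4826 * np.median(np.abs(x - med))
    if mad_sd == 0:
        mad_sd = np.std(x) or 1.0
    mask = np.zeros(len(windows), dtype=bool)
    if not np.isfinite(threshold_sd):
        return mask
    limit = threshold_sd * mad_sd
    for w, (a, b) in enumerate(windows):
        i0 = int(np.clip(round((a - trace.t0) * trace.fs), 0, trace.n))
        i1 = int(np.clip(round((b - trace.t0) * trace.fs), 0, trace.n))
        if i1 > i0 and np.max(np.abs(x[i0:i1] - med)) > limit:
            mask[w] = True
    return mask
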