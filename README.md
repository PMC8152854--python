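# kindleictal

Electrographic seizure analysis for chronic-kindling EEG: rule-based
detection of spontaneous discharges and their onset types, wavelet-based
phase-amplitude coupling with peri-ictal averaging, wavelet phase coherence
between paired recording sites, and classification of in-vitro
field-potential events — all testable end to end against a synthetic-data
generator with exact ground truth.

## Who this is for

Electrophysiologists analysing intracranial EEG from rodent epilepsy models
(and the slice recordings that accompany them) who need reproducible,
scriptable versions of the analyses usually done semi-manually in
acquisition software: recognising spontaneous discharges, distinguishing
low-voltage-fast (LVF) from hypersynchronous (HYP) onsets, quantifying
cross-frequency coupling over the course of a seizure, and asking whether
two recording sites are phase-locked.

## The analyses

**Discharge recognition.** A spontaneous discharge is a run of repetitive
spikes with amplitudes ≈2× the background signal lasting ≥ 10 s, terminated
by abrupt spike cessation followed by voltage suppression. Signals are
band-passed 2–200 Hz (8-pole Bessel, applied forward–backward for zero
phase) before measurement. An LVF onset is an abrupt attenuation of
background to ≤ 65 % of the preceding amplitude lasting 0.5–5 s before
repetitive spiking; a HYP onset is an immediate cluster of large spikes;
incremental onsets ramp up from baseline. LVF strength is quantified as
100 · SD(LVF window) / SD(preceding window).

**Phase-amplitude coupling (PAC).** Phase φ(t, f_L) and amplitude A(t, f_H)
come from the complex Morlet continuous wavelet transform (mother wavelet:
centre frequency 0.8125 Hz, bandwidth parameter 5), with f_L on a log grid
over 1–30 Hz and f_H over 32–512 Hz. Coupling strength is the
Tort-style modulation index

    MI = KL(p ‖ uniform) / log N,    p_k ∝ ⟨A⟩ in phase bin k,

with N = 18 bins of 20°, evaluated in non-overlapping 4-s windows (≥ 4
cycles of every phase band) and averaged spectrally and temporally over
peri-ictal segments: preictal [t_on−8, t_on), onset [t_on, t_on+8), ictal
[t_on+8, t_off−8), offset [t_off−8, t_off), postictal [t_off, t_off+8).
Windows containing large movement artifacts are excluded.

**Wavelet phase coherence (WPC).** For two aligned channels,
Δφ(t, f) = arg(W₁*(t, f) · W₂(t, f)) and ρ = |⟨e^{jΔφ}⟩| over windows of
8 cycles of each analysis frequency (0.25–512 Hz, log-spaced); ρ = 1 is a
phase lock, and for independent signals the across-window coherence floor
is the resultant-length bias √(π/4n) for n windows.

**In-vitro events.** Sharp waves: ≈2× background, base duration 20–200 ms,
incidence 0.3–4 events/s over 1-min segments. Interictal spikes: ≥ 0.5 mV,
200–600 ms, 2–5 events/10 s (threshold search after an optional 0.2–500 Hz
Bessel band-pass). Ictal discharges: peaks ≥ 1 mV, with mean duration
≥ 30 s and mean interevent interval ≥ 90 s for an ictal-bearing trace.

**Group statistics.** Per-subject segment PAC is compared between groups
with the two-sided Mann–Whitney U test (exact for n ≤ 12 without ties).

## Worked example

Recover a planted coupling from a synthetic 60-s trace (8 Hz phase
modulating an 80 Hz carrier at full depth, on 1/f background):

```python
import numpy as np
from kindleictal.synthdata import SynthConfig, CouplingSpec, generate_pac_signal
from kindleictal.coupling import pac_windows, default_phase_grid, default_amp_grid

cfg = SynthConfig(duration=60, fs=1250, seed=1)
trace, truth = generate_pac_signal(CouplingSpec(f_phase=8, f_amp=80, depth=1.0), cfg)
series = pac_windows(trace, default_phase_grid(), default_amp_grid())
com = series.mean_comodulogram()
f_p, f_a = com.argmax_pair()
print(f"planted (8, 80) Hz; recovered ({f_p:.2f}, {f_a:.2f}) Hz")
print(f"peak MI {np.nanmax(com.mi):.4f} over {series.n_windows} four-second windows")
```

prints

```
planted (8, 80) Hz; recovered (7.70, 90.51) Hz
peak MI 0.0551 over 15 four-second windows
```

The recovered pair sits on the log grid points nearest the planted
frequencies (within one grid step on each axis at 4 points/octave); the
peak MI of 0.055 reflects the wavelet's constant-Q envelope smoothing and
the 1/f noise floor — depth 0 on the same noise gives MI ≈ 10⁻⁵.

The numbered scripts under `analysis/` run the full study flow —
simulation, detection benchmarks, PAC recovery, coherence, slice events,
group comparison — and write their tables to `results/`. The `kindle-ictal`
CLI exposes `simulate`, `detect`, `pac`, `wpc` and `run` for shell use on
CSV/EDF traces.

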