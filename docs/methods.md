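# Methods

This note documents the models, parameter choices, numerical details and
known limitations of the package. The detection rules and coupling
definitions themselves are stated in the README; here we record *how* they
are implemented and *why* the open choices were made the way they were.

## Signal model and synthetic data

The generator produces the statistical structure every downstream stage
assumes, with exact ground truth, so the whole pipeline is testable without
recordings.

**Background.** Gaussian noise spectrally shaped to 1/f^α (α = 1 by
default), flattened below 0.5 Hz to keep total power finite, rescaled to an
exact sample SD. This emulates the broadband LFP floor that the "2×
background" amplitude rules reference. For slice traces the default is
α = 0 (white): the baseline of submerged-slice field-potential recordings
is dominated by near-white instrumentation noise, and a 1/f baseline
produces 20–200 ms excursions above 2 SD that are statistically
indistinguishable from the sharp-wave class itself. Passing a different α
reproduces that regime deliberately.

**Discharges.** Biphasic spikes (difference of Gaussians, 40 ms default
width) on jittered-rhythmic trains (inter-spike intervals uniform ±25 %
around the rate profile, 8/s sustained). Rhythmic rather than Poisson
trains are used deliberately: at onset-ramp rates a Poisson train
occasionally produces gaps longer than the 2-s spike-gap tolerance, which
would split a planted event and make the ground truth inconsistent with
the recognition rule the event was built to satisfy. LVF onsets multiply
the running background by the attenuation fraction for the stated window,
then ramp spike rate and amplitude in; HYP onsets start with a 4-spike
full-amplitude cluster inside the first second; incremental onsets ramp
rate (2→8/s) and amplitude (1.5→5 SD) over 40 % of the event. Termination
is followed by a suppression segment (background × 0.3). Default spike
amplitude is 5 background SDs, i.e. roughly 2× the background's visible
peak amplitude (see below) — SNR ≥ 3 conditions throughout.

**Coupling.** The PAC trace is
`carrier_amplitude · (cos φ_L + env(φ_L) · cos 2π f_H t)` plus background,
with `env = (1−depth) + depth·(1+cos φ_L)/2`, so depth 0 gives a
phase-independent envelope and depth 1 an envelope that vanishes at the
anti-preferred phase. Default carrier amplitude is 3× the background SD.
Coherent pairs share a narrow-band (±¼-octave Butterworth-filtered noise)
component scaled by `lock_fraction`, plus independent noise scaled by
`1 − lock_fraction`; a constant per-channel gain and phase lag are applied
to the shared part.

**Slice events.** Gaussian field events whose width is solved so that a
threshold walk at the detector's base level recovers the planted base
duration exactly; ictal events are 6-Hz oscillatory bursts under a Tukey
envelope. Event trains are jittered-regular; later plants shift off
occupied intervals (or are dropped) so planted events never overlap, and
overlapping ictal bursts raise an error. Each ground-truth row carries a
`meets_criteria` flag computed from the detection rules, so sub-threshold
plants (0.4 mV amplitude, 250 ms sharp-wave width, 0.1/s incidence) serve
as negative controls.

Every generator is a pure function of (config, seed); identical inputs give
bit-identical output.

**What the generator does not emulate.** Real spike-waveform diversity,
state-dependent background (sleep/wake), electrode drift, chewing/EMG
artifact spectra, true propagation delays between structures, and any
biophysics (no neural-mass or network model). Passing benches on this
synthetic family therefore shows the *rules are implemented correctly and
are recoverable under realistic noise*, not that the detector generalises
to arbitrary recordings.

## Detection details

**Background level.** "2× the background signal" compares spike amplitude
with the background's *visible amplitude*, not its SD: peaks of
Gaussian-like background reach 2–3 SDs routinely, so thresholding at 2×SD
fires continuously on event-free signal. The detector therefore uses
`amplitude_factor × 2.33 × SD_robust`, where 2.33 × SD is the 98th
percentile (typical peak height) of Gaussian background and SD_robust is
MAD-scaled. The reference SD comes from a pre-event window (up to 30 s
before the spike train, clear of the previous event), with a whole-trace
fallback taken as the 25th percentile of 1-s block MADs — the quietest
quarter of the trace — so long discharges never inflate their own
threshold.

**Event assembly.** Suprathreshold peaks of the 2–200 Hz signal separated
by gaps ≤ 2 s form trains; trains shorter than 10 s are discarded.
Termination is the last suprathreshold spike; a confirmation flag records
whether the following 2 s stay below 1.5× background (the suppression
signature). Events are merged if they overlap after refinement.

**LVF anchoring.** The onset is anchored at the attenuation crossing, not
at the (variable) preceding spike: the 0.25-s rolling SD is compared with
65 % of the pre-event background, sub-0.3-s excursions are bridged
(short-window SD fluctuates on 1/f background), and the latest run ≥ 0.5 s
ending within 3.5 s of the first detected spike moves the onset to its
start. The 3.5-s allowance covers incremental spikes that are genuinely
part of the discharge but below the detection threshold. The first-spike
time is kept as an auxiliary field.

**Classification order.** LVF is tested first (attenuated window with
normalized SD ≤ 65 %); then HYP (≥ 3 spikes ≥ 2 SD in the first second at
near-steady amplitude); then incremental (positive amplitude ramp starting
below 60 % of steady); otherwise unclassified. No human-adjudication step
exists; borderline events simply fall through to UNCLASSIFIED.

**In-vitro detectors.** Peak search and base-duration walks run on a
boxcar-smoothed copy of the signal (10 ms for sharp waves, 20 ms for
interictal/ictal — far below the minimum base durations), because
sample-level noise otherwise fragments threshold-walked extents. Incidence
rules gate acceptance per segment (1 min for SPWs, 10 s for interictal
spikes): events in segments whose rate falls outside the stated range are
rejected. A trace is ictal-bearing only if mean event duration ≥ 30 s and
mean interevent interval ≥ 90 s (vacuous for a single event). The
interictal 0.5 mV rule is absolute, so traces must carry mV units; a
unit error is raised otherwise. Mixed traces combine sharp waves and
interictal spikes; the ictal/interictal dichotomy is assessed per trace,
matching how slices express one regime or the other.

## Wavelet transform

The mother wavelet is ψ(t) = (π·fb)^(−1/2) · e^{j2πfc·t} · e^{−t²/fb} with
fc = 0.8125 Hz and fb = 5. A bandwidth parameter of 5 for a 0.8125-Hz
centre is an unusual (>1 fractional-bandwidth) pairing; it is implemented
literally as the Gaussian-envelope parameter and both values are exposed
for sensitivity checks. The daughter at analysis frequency f is the mother
dilated by s = fc/f (standard constant-Q convention; the scale–frequency
mapping is a documented choice). In the frequency domain
Ψ_f(ν) = exp(−π²·fb·fc²·(ν/f − 1)²) for ν > 0, applied analytically
(negative frequencies zeroed, positive doubled) by FFT multiplication with
padding to the next power of two ≥ 2n — numerically equivalent to direct
convolution. A unit cosine at f yields |W| ≈ 1 on its own row.

Phase is the four-quadrant angle of the coefficient (a quadrant-blind
arctan of Im/Re cannot represent (−π, π]); amplitude is the complex
modulus. A cone-of-influence mask flags coefficients within one envelope
e-folding time (√fb · fc/f ≈ 1.8 cycles) of either edge.

Log grids are geometric sequences containing both endpoints exactly, with
the interval count rounded to the requested points per octave.

## PAC numerics

Phases are binned over (−π, π] into 18 equal bins; −π folds into bin 0.
Empty bins contribute p_k = 0 (0·log 0 := 0); identically zero amplitude
returns NaN with a warning. Normalization is by log 18, so MI = 1 is the
single-bin limit. Windows are non-overlapping 4-s tiles from the trace
start; phase rows with fewer than 4 cycles per window are flagged
unreliable and skipped by spectral averages. Artifact exclusion masks any
window containing a sample beyond 8 robust SDs of the trace median
(configurable; ∞ disables). Spectral averaging (grid mean over reliable
rows) precedes temporal averaging (over the segment's unmasked windows);
the two orders agree only when window counts match, and this order is the
documented choice. A window belongs to the peri-ictal segment containing
its centre. Segments with no usable window are reported missing rather
than zero.

## WPC numerics

Δφ is the cross-spectrum phase angle(W₁*·W₂) = φ₂ − φ₁. (A literal
transcription of the printed ratio form would use a denominator
W₁W₂ − W₁*W₂*, which is not the cross-spectrum modulus and breaks the
stated ρ = 1 property for identical signals; the cross-spectrum form
restores it and equals the intended phase difference.) Per frequency,
unit phasors are averaged over non-overlapping windows of 8/f seconds:
the windowed resultant ρ ∈ [0, 1] is the time-resolved map. The
per-frequency summary `band_coherence` is the resultant of one phasor per
window taken at the window *centre* sample: centres lie 8 cycles apart,
far beyond the wavelet decorrelation time (≈1.8 cycles), so under
independence these are n iid uniform phasors and the summary obeys the
analytic E[ρ] = √(π/4n) resultant-length bias. Window-*mean* phasors are
slightly correlated across boundaries and would sit ≈10 % above that law,
which is why the centre-sample convention is used for the summary.

## Filters

The 8-pole Bessel band-passes (2–200 Hz EEG, 0.2–500 Hz slice) are
implemented as order-8 digital Bessel designs applied forward–backward
(zero phase, so onset times are unbiased; the magnitude response is
squared). Corner frequencies are pre-warped by per-edge root-finding so the
−3 dB points of the *combined* response sit at the stated corners. The
60 ± 3 Hz notch is an IIR notch (Q = 10) applied forward–backward.
Downsampling uses polyphase resampling with its built-in anti-alias filter
and accepts rational factors; it warns (or errors) when the new Nyquist
falls below a requested analysis band, e.g. 5000→1000 Hz under a 512-Hz
PAC band.

## Pipeline and statistics

Paired analysis detects and classifies per channel, matches events
one-to-one across channels by onset proximity (≤ 5 s), and reports events
present in only one channel separately — they are listed, not analysed,
mirroring the inclusion rule that paired analysis requires decipherable
events in both recordings. Onset concurrence is reported purely
descriptively (difference in seconds); no directionality claim is
attached. PAC amplitude grids are capped below the channel Nyquist when a
recording cannot support the full 32–512 Hz band.

Group comparison is a two-sided Mann–Whitney U: exact when both groups
have ≤ 12 values and no ties, otherwise normal approximation with tie
correction; a perfectly balanced statistic (U = n₁n₂/2, e.g. identical
groups) returns p = 1 by convention. Per-subject summarization (one value
per subject per segment) precedes testing, avoiding pseudo-replication.
Because the exact test is discrete, its true size at nominal α = 0.05 is
the largest attainable level below α (4.11 % at n = 6 per group); the null
calibration bench compares the observed rejection rate on coupling-free
synthetic studies against that achievable level, not against 5 %.

## Benchmark problem sizes

In-vivo benches run at 1000 Hz — the discharge rules involve nothing above
200 Hz, and the acquisition-rate default (5000 Hz) is kept for I/O and
slice benches where the rules reference finer structure. The detection
bench plants 50 events of 15–60 s; PAC recovery uses a 60-s trace at
1250 Hz with full 4-points/octave grids; depth monotonicity uses 20 seeds
× 5 depths with single-frequency transforms at the planted pair; the WPC
null uses 200 independent pairs of 10 windows; the calibration bench runs
200 studies of 12 subjects on reduced 1-point/octave grids (only the
test's calibration, not PAC resolution, is at stake there). These sizes
are the package's benchmark conditions and are fixed in
`kindleictal/benchmarks.py`.

## Known limitations

- The 2-s spike-gap tolerance and 2-s suppression check quantify
  "several seconds" phrasing that has no unique value; both are exposed in
  `DetectionParams`.
- Whether the amplitude rule applies to raw or filtered signal is
  ambiguous in the field; it is applied to the 2–200 Hz filtered signal
  here.
- EDF writing pads traces to whole seconds (1-s records, 16-bit); readers
  see the padded length.
- The comodulogram's effective frequency resolution is set by the
  constant-Q wavelet (±≈15 % half-power); planted couplings are recovered
  to one grid step, not exactly.
- `wpc` assumes sample-aligned traces and raises otherwise; no resampling
  or lag search is attempted.
- Classification of incremental onsets on real data likely needs tuning;
  only LVF/HYP discrimination is benchmarked.
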