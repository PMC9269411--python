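# Methods

This note records the model underlying the synthetic data, the statistical
procedures, the defaults and the numerical choices, together with the
reasoning behind the decisions the design left open.

## Stimulus protocols

Two AM protocol families are generated as fully enumerated event tables.

**Cardinal.** Gabor strokes are flashed along the RF's orientation-preference
("main") axis and its orthogonal width axis, one side at a time, with
frame-locked strokes of one 60 Hz frame (16.67 ms). Geometry follows the
spiking discharge field: patch mask = 150% of the MDF length, Gaussian
envelope sigma = 20% of the mask, inter-node spacing = 120% of the mask.
The Surround-Only study enumerates 8 flow configurations (CP/CF × ISO/CROSS
× main/width) × 2 directions + Center-Only + Blank = 18 conditions; the
Center–Surround study enumerates 4 configurations × 2 directions +
Center-Only + Blank = 10. In centrifugal (CF) sequences the (shown or
omitted) center stroke leads the flow; every sequence carries an
`expected_center_onset_ms` — the time at which the center stroke occurs or
would have occurred — and all analyses realign on it.

**Radial.** Five concentric rings spaced by the SRF extent (so no surround
node overlaps the SRF; a spacing below the SRF extent is rejected as invalid
geometry), stroke duration 30 ms by default (configurable ±9 ms), patch mask
equal to the SRF extent. A block holds 16 AM sequences (CP-ISO, CF-ISO,
CP-CROSS, RND-ISO × with/without center × SECTOR/FULL), 21 isolated-Gabor
stimulations (5 rings × ISO/CROSS × SECTOR/FULL + 1 center Gabor) and 6
blanks — 43 entries, presented once each per block in seeded random order.
SECTOR stimulates both opposite sides of an axis simultaneously (symmetric
flow); angular offsets default to −30…+30° in 15° steps per side and are
configurable, since the node-pool size is a free layout choice once the
geometry rules are fixed. RND-ISO permutes the ring order of the matched
CP-ISO sequence on the same onset grid (energy-conserving), is re-randomized
every block, and always ends at the center in full sequences.

Default contrasts are 0.925 (surround) and 0.406 (center) — the across-cell
mean values of the protocols being emulated. `scale_speed` stretches
inter-stroke onsets by 1/fraction while leaving stroke durations unchanged.

## The synthetic generator

A trial is `Vm(t) = v_rest + OU(t) + Σ_k A_k·K(t−o_k)` with:

- **PSP kernel** `K`: unit-peak double exponential (rise 5 ms, decay 30 ms).
  Chosen over a single alpha function for independent rise/decay control
  with an analytic peak.
- **Lateral volleys**: one PSP per surround *stroke group* (all Gabors
  flashed at one onset act as one volley). Onset
  `o = stroke_onset + base_latency + ecc·M/ashp_true`; amplitude
  `A = a0·exp(−ecc/λ)·contrast`, further multiplied by
  `cross_orientation_gain` (default 0.3) when the inducer is more than 45°
  from the cell's preferred orientation — the iso-orientation bias of
  horizontal connectivity, needed for CP-ISO/CP-CROSS asymmetries to exist
  in synthetic data.
- **Feedforward PSP** per center (D0) stroke: onset `base_latency`,
  amplitude `ff_amplitude·contrast`.
- **Gated supra-linear interaction** (off by default): every PSP's amplitude
  is multiplied by `1 + interaction_gain · V_lat(o_k)/a0`, where `V_lat(o_k)`
  is the depolarization accumulated from lateral volleys that precede this
  PSP's onset by more than `interaction_lag_threshold` (5.5 ms). This single
  mechanism makes both the Surround-Only build-up and the final feedforward
  response supra-linear when lateral input leads, and reduces exactly to
  additivity at gain 0.
- **Background noise**: stationary Ornstein–Uhlenbeck process (σ default
  2 mV, τ default 20 ms), the simplest process with controllable variance
  and correlation time resembling ongoing synaptic noise.
- **Spikes**: upward threshold crossings (default −57 mV on a −67 mV rest)
  with a 3 ms absolute refractory period; a stereotyped 1 ms alpha-shaped
  spike waveform (+45 mV) is superimposed so the spike-removal stage of the
  analysis is genuinely exercised. No adaptation.
- An optional `soft_clip_reversal` tanh saturation emulates sub-linear
  summation near the reversal potential; off by default.

Defaults: `ashp_true` 0.2 mm/ms (center of the physiological 0.05–0.60
range), `base_latency` 35 ms, magnification 1 mm/deg (the value under which
150–250 deg/s visual flow equals 0.15–0.25 mm/ms cortical speed), `a0`
3.5 mV and `λ` 10° (surround responses of 1–4 mV over the probed
eccentricities), `ff_amplitude` 18 mV per unit contrast (≈7.3 mV at the
default center contrast, matching example-cell magnitudes).

Everything is deterministic given a seed; dataset generation stores per-cell
parameters, seeds and a protocol hash in the dataset metadata.

## Preprocessing

Spikes are excised over a −0.5/+6 ms window and replaced by
`v0 + a·t·exp(−t/τ)`, with `a` the Vm slope at the peak of the second
derivative of the rising phase and `τ` the spike half-width, spliced with a
1 ms linear blend at the window end (the blend length is a choice; the
replacement anchors exactly at the window-start voltage). Spikes closer than
their width are merged into one replacement and logged.

Conditioning band-passes 0.1–300 Hz with zero-phase (forward–backward)
Butterworth filters — zero-phase because latency is a measured quantity and
causal filtering would bias it. The band is realized as separate high-pass
and low-pass sections (a single band-pass spanning 3.5 decades at 10 kHz is
numerically ill-conditioned), applied to the mean-removed trace with the
mean restored afterwards so conditioning commutes with additive constants.
On traces shorter than one high-pass period (10 s) the 0.1 Hz corner is
below the trace's frequency resolution and the mean removal implements it.
Traces are then FIR-decimated to 1 kHz and smoothed with a 7 ms sliding
average. PSTHs are built at 1 ms resolution and smoothed with a Gaussian
window (σ = 3 ms); rates are in spikes/s so one spike per trial integrates
to 1. The 7 ms average and blank subtraction are both linear, so their order
is immaterial; block-mean subtraction removes each block's scalar mean
activity.

## Statistics

**Thresholded integrals** (cardinal-style): baseline mean and SD from 100 ms
of pre-stimulus activity; the response is integrated where it exceeds the
one-sided 95% bound (z = 1.645) over 0–250 ms, giving a non-negative mV·ms
measure that is invariant to baseline shifts.

**Permutation envelopes** (radial-style): trial labels are exchanged between
two pools (condition vs. blank, observed vs. predictor), 10⁴ permutations by
default, exhaustively enumerated whenever the number of distinct assignments
is smaller. Trial-label exchange is the natural exchangeable unit when
trials are interleaved within blocks. Pointwise quantiles give the envelope;
significance additionally requires the observed mean to stay above the upper
bound for a minimum consecutive duration (1 ms for Surround-Only screening,
7 ms against the linear predictor, 15 ms for the conservative variant — all
exposed as parameters, since different reported screens use different
durations).

Two refinements keep the *verdict-level* error calibrated:

- **Studentization** (used in the supra-linearity test): predictor trials
  assembled by summing five component trials have ≈5× the variance of
  observed trials; the pointwise Welch-t statistic restores exchangeability
  under variance heterogeneity.
- **Duration calibration** (same test): with noise correlated over ~20 ms,
  any pointwise exceedance tends to persist beyond a fixed 7 ms floor, so an
  "any run ≥ 7 ms" rule alone has a 25–30% familywise rate over a 120 ms
  window. The required run length is therefore raised to the (1 − α)
  quantile of the null maximal supra-bound run, computed from the same
  permutations; the stated minimum duration remains the floor. Measured
  false-positive rate under the additive generator: ≈0.08 at α = 0.05
  (binomially consistent with the nominal level).

**Latencies**: the three-sigma rule (first departure from the blank mean by
more than 3 blank SDs) and the half-height rule (first crossing of half the
Center-Only peak) are both interpolated between samples. The crossing is
anchored to the excursion containing the response peak — walking back from
the peak to the last sub-criterion sample — so isolated pre-stimulus noise
blips cannot masquerade as onsets. Undefined latencies are returned as NaN
and excluded (never imputed) from regressions and summaries.

**Contextual modulation**: Δ-latency = latency(Center-Only) − latency(test)
at half the Center-Only peak; Δ-integral = thresholded-integral ratio
test/Center-Only. One-sided permutation p-values (facilitation direction)
by trial-label exchange, with the latency and integral statistics recomputed
on each permuted split (vectorized). Per-condition tests are reported
without multiple-testing correction, matching the per-condition reporting
convention; an FDR pass can be applied downstream to the p-value columns.

**Propagation**: the latency basin is an ordinary least-squares fit
(latency ~ eccentricity) via statsmodels; `ashp = magnification/slope`, with
a non-positive slope flagged as "no propagation signature" rather than a
number. The bilinear phase fit searches breakpoints exhaustively over the
observed phases and their midpoints; with the connexity constraint each
candidate is a hinge regression solved by least squares, and per-segment r²
and n are reported (an independent-halves toggle fits two unconstrained
half-lines). KDE summaries use Gaussian kernels with Silverman bandwidth.

**Population**: waveforms are normalized to each cell's Center-Only peak and
shifted so the Center-Only 3σ onset sits at time 0, then resampled at 1 kHz
on the intersection window and averaged with SEM envelopes. Because rise
times vary across cells, the population peak is generally below 1. The
orientation frame is cell-centric by construction of the protocols, so no
extra rotation is needed at averaging time. Speed tuning summarizes, per
replay fraction (1.0/0.7/0.5/0.3), the population mean of the per-cell peak
contextual amplitude (AM response minus Center-Only).

## What the generator does and does not emulate

It reproduces: the latency/amplitude laws of lateral input, interleaved
blocks with blanks, cell-to-cell parameter heterogeneity via priors,
orientation-biased lateral recruitment, optional supra-linear synergy,
threshold spiking, and trial-to-trial OU variability.

It does not emulate: conductance-based membrane dynamics or reversal-driven
sub-linearity (beyond the optional soft clip), orientation-map structure or
network reverberation, eye movements, slow excitability drift across blocks,
or the non-specific "Near-surround" feedforward contamination of the
cardinal protocol (exposed as an optional additive term without a calibrated
default, since no amplitude is available to anchor it). Passing tests on
synthetic data therefore validate the *analysis machinery* and the internal
consistency of the model — not the biological claims themselves. One known
interaction: spike-replacement residue adds depolarization to spiking trials
that is absent from isolated-response predictors, which can register as
supra-linearity in strongly spiking cells; subthreshold validation runs
disable spiking.

## Problem sizes and numerical choices

The demo dataset is 3 cells × 20 blocks × 43 radial entries (2,580 trials at
10 kHz) with 10³ permutations per test, chosen as the smallest dataset on
which every pipeline stage (screening, per-condition modulation, SLP,
latency basin, population averaging) is exercised with stable statistics;
it completes in well under a minute on one CPU. Parameter-recovery studies
use 5 eccentricities × 20 trials at noise σ = 1 mV, a₀ = 4 mV, λ = 20°
(amplitudes 2.2–3.7 mV over 2–10°, i.e. comfortably detectable but far from
noise-free), recovering ASHP within 10% across the 0.1–0.4 mm/ms range.
Calibration studies use 500 Monte-Carlo runs with 10³ permutations.
Quantile methods are `higher`/`lower` (conservative on discrete nulls);
degenerate inputs (empty pools, flat references, all-NaN latencies,
single-speed tables) raise or degrade explicitly rather than silently.
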