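# Methods notes

This note records the models, conventions and deliberate choices behind
ephysforge, in enough detail that a maintainer can judge what the package's
passing tests do and do not establish.

## Signal model of the simulator

### Spike-band recordings

The simulator emulates a 32–64-channel wideband recording at 25 kHz in
which each 16-wire cannula bundle forms one polytrode group:

- **Templates.** Biphasic action-potential shapes: a narrow Gaussian trough
  followed by an asymmetric Gaussian repolarization peak. The trough-to-peak
  gap sets the *peak-to-trough width*; the falling flank of the peak is
  sized so the tail stays above 20% of the peak for exactly the planted
  *afterhyperpolarization (AHP) duration* (a Gaussian tail crosses the 20%
  level at σ·√(2 ln 5) after the peak). Two cell classes draw their
  (width, AHP) from disjoint ranges — fast-spiking putative interneurons
  0.15–0.30 / 0.15–0.35 ms, putative excitatory cells 0.45–0.70 /
  0.50–0.80 ms — so the class dichotomy is separable by construction.
- **Footprints.** Channel gains decay geometrically with nominal wire
  distance from a primary wire (decay drawn in 0.12–0.30), leaving 1–4
  wires above 20% gain, matching the few-sites-per-unit overlap of brush
  electrode bundles. Primary wires are assigned *without replacement*
  within a bundle: each wire sees at most one nearest neuron. Without this,
  two same-class units can land on the same wire with near-identical
  waveforms and are unsortable in principle; the distinct-wire regime is
  what the sorter (and any sorter) assumes.
- **Spiking.** Homogeneous Poisson trains with an absolute dead time:
  intervals shorter than the refractory period (default 3 ms) are censored,
  so ground-truth trains have zero ISI violations by construction. Default
  rates are drawn uniformly from 2–8 Hz, bracketing the ~4–5 Hz session
  averages typical of rat frontal cortex.
- **Rendering.** Spike insertion is additive and linear (overlapping spikes
  superpose); background noise is white Gaussian in the spike band.
  Default template peak-to-peak is 110 µV over 10 µV noise, i.e. a trough
  amplitude ≈ 8× noise SD — a deliberately clean, well-isolated regime.

### LFP sessions

32 electrodes at 1 kS/s: per-electrode 1/f (power ∝ 1/f) background plus a
shared common-mode component, event-locked Hann-windowed sinusoidal bursts
per oscillation spec (optionally restricted to a trial type), and trial
types drawn 75% "wait" / 25% "go". A configurable fraction of trials
receives a broadband artifact: Hann-enveloped white noise at 15× the
*realized* background SD (noise + common mode) spanning the epoch window.
Scaling to the realized background rather than the white-noise parameter
keeps the artifact "high-amplitude" in the sense the rejection rule sees.

### Multi-session series

Sessions share one deterministic signal tensor (SD σs) plus independent
per-session noise (SD σn), so the expected intraclass correlation is the
closed form σs²/(σs²+σn²). This gives exact targets ICC = 1, 0.5 and 0 for
variance ratios ∞, 1 and 0.

### What the simulator does *not* emulate

No biophysical neuron models, electrode drift, bursting or rate
non-stationarity, spike-waveform variability beyond additive noise, no
volume-conducted spike bleed across bundles, no behavioral learning. A
passing recovery test therefore shows the chain is correct and
well-calibrated under clean, stationary, well-separated conditions — not
that it matches curated manual sorting on real tissue.

## Sorting chain decisions

- **Noise SD estimator**: robust σ̂ = median(|v|)/0.6745 per channel, so
  spikes do not inflate their own detection threshold; the plain SD is a
  config switch.
- **Detection** is bipolar (|v| crossings) by default; window 0.8 ms pre /
  1.7 ms post (62 samples at 25 kHz); events within the snippet length on
  one channel merge to the largest excursion, and crossings within ±0.5 ms
  across a group's wires collapse to the largest-amplitude channel.
  Alignment is to the absolute-extremum sample near the crossing.
- **Features**: per-wire 4-level Haar decompositions of the aligned
  snippets, concatenated; coefficients ranked by the one-sample
  Kolmogorov–Smirnov statistic against a fitted Gaussian (ties broken by
  variance, then index). Each wire's best coefficient is always retained
  before the remaining slots fill by global rank — purely global ranking
  can leave a low-count unit's wire entirely unrepresented, making that
  unit invisible in feature space. Default 24 coefficients: a concatenated
  16-wire snippet carries an order of magnitude more coefficients than the
  single-wire snippets for which a 10-coefficient default was designed.
  Under 10 events, principal components substitute (flagged by negative
  indices).
- **Clustering**: the cluster count is chosen by the algorithm, not fixed —
  diagonal-covariance Gaussian mixtures on standardized features, k = 1–10,
  best BIC wins; k-means++ initialization with 5 restarts; deterministic
  given the seed. Monte-Carlo superparamagnetic clustering is intentionally
  not reproduced: the contract is any seedable, count-selecting clusterer,
  and the acceptance surface is planted-unit recovery.
- **Merging**: pairs with mean-waveform Pearson r ≥ 0.95 merge if the
  merged ISI-violation fraction stays within the 1.5% acceptance limit;
  iterated to a fixed point, hence idempotent.
- All detected events are assigned to some cluster; there is no separate
  unassigned pool. Noise events form their own low-amplitude clusters that
  the QC stage rejects (sub-threshold rate, non-biphasic mean waveform, or
  peak-to-peak < 4× residual RMS), which covers the same ground.

## QC conventions

- **SNR** uses the referenced, band-passed trace of the unit's best channel
  with *all* detected spike windows excised from the residual; excision
  stops spikes inflating the noise RMS. Note the calibration consequence:
  on band-limited noise the estimate equals amplitude/noise-SD of the trace
  it sees; relative to the wideband simulator parameters, band-passing
  roughly halves the noise RMS, so pipeline SNRs run about twice
  peak-to-peak/wideband-σ.
- **"Waveform resembles an action potential"** and **"cluster is
  distinct"** were manual judgments in the source workflow; here they are
  automatic flags (biphasic trough-then-peak shape with p2p ≥ 4× residual
  RMS; separation flag accepted by default and overridable) so the chain
  runs unattended.
- **AHP duration** has no standard operational definition; the convention
  here is the time the post-peak tail stays above 20% of the peak. It is a
  declared convention, not a community standard; the simulator plants AHPs
  under the same definition, so recovery tests exercise measurement, not
  the convention itself.
- **PSTH** bin width defaults to 50 ms with a 500 ms pre-response baseline;
  per-bin paired t-tests are uncorrected by default (a Benjamini–Hochberg
  switch exists) to mirror the reporting style of the source workflow.
- **E/I classification**: k-means, k = 3, on (width, AHP); the cluster with
  the smallest centroid on both features is labeled inhibitory, the largest
  excitatory, the middle outlier. With only two genuine populations the
  forced third cluster absorbs boundary units — visible in the README
  example. Under 3 units, nearest-of-two fixed reference centroids.

## LFP chain decisions

- **Cycles convention.** The two-element cycles parameter [2, 0.7] is read
  as the expanding-wavelet rule c(f) = c₀·(f/f_min)^(1−q) with c₀ = 2,
  q = 0.7 — so c(2 Hz) = 2 and c(70 Hz) = 2·35^0.3 ≈ 5.81. This is the
  widely used reading of a two-element cycles argument (constant cycles at
  q = 1, fixed FFT-like window at q = 0), but it is an *interpretation*,
  config-switchable via `cycles_factor`.
- **Frequency grid**: 40 log-spaced frequencies, 2–70 Hz (linear available).
- **Edges**: samples whose wavelet support leaves the epoch are NaN, never
  zero-padded, so baselines cannot include edge artifacts. At 2 Hz with
  3.5σ truncation this invalidates ≈ 0.56 s at each epoch edge — epochs
  must be cut generously around the baseline window.
- **Wavelet normalization**: unit gain for a unit-amplitude sinusoid at the
  wavelet's center frequency, so TF amplitudes read in µV.
- **Artifact statistic** runs on raw (pre-referencing) epochs, matching the
  stage order of the source workflow; the state flag enforces this.
- **Z-scoring** is per (electrode, frequency) across time, applied per
  session before any cross-session averaging; zero-SD slices map to 0 and
  are flagged rather than raising.
- **ICC form**: the source workflow does not name its variant; ICC(2,1) —
  two-way random effects, absolute agreement, single rater — is the
  declared default, computed from the two-way ANOVA mean squares and
  cross-checked in tests against an independent implementation. LFP
  baseline duration (unstated upstream) defaults to 500 ms for symmetry
  with the PSTH baseline.
- The TF output time axis is decimated to 10 ms steps; full-rate output
  would multiply memory ~10× with no analytical benefit at ≤ 70 Hz.

## Problem sizes in tests

Recovery tests run a 60 s, 32-channel session (10 units, ~3,000 spikes) —
large enough that per-unit recall/purity estimates are stable, small enough
to run routinely. Calibration loops (SNR, artifact rejection, E/I mix) use
20 / 20 / 10 independent seeds; ICC checks use 20 sessions × 10⁴ bins per
electrode, where the sampling SD of ICC at 0 is well under the 0.05 band
asserted.

## Known limitations

- No cross-session unit tracking, drift handling or online sorting.
- Vendor acquisition formats are out of scope; the flat-binary + JSON
  sidecar contract documents what a converter must produce.
- The GMM clusterer degrades when units share a wire with highly similar
  waveforms (physically coincident cells); the simulator's distinct-wire
  assignment reflects, rather than hides, this limit.
- Connectivity metrics (e.g. phase-lag indices) and bipolar re-referencing
  are intentionally absent.
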