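# Methods

This note documents the models and numerical choices behind
`fiberbehav`: a pipeline for quantifying how a midbrain locomotor
circuit (GABAergic zona incerta projections onto the cuneiform
nucleus) relates to exploratory behavior. It covers four analysis
surfaces — isosbestic-referenced fiber photometry, threshold-based
behavioral-state classification, optogenetic unit-responsiveness
testing, and synaptic-puncta colocalization — plus the synthetic-data
generators used to validate them.

## Fiber-photometry processing chain

A session carries a calcium-dependent 465-nm signal and an isosbestic
405-nm reference on one time base. The chain, applied in fixed order
and recorded in the trace's provenance list:

1. **Decimation** (optional, acquisition-side, default ×100) by
   polyphase FIR with linear edge padding, chosen over IIR decimation
   because it passes DC and linear trends exactly.
2. **Resampling** to a uniform grid (default 100 Hz) by linear
   interpolation; jittered acquisition timestamps become an exact
   1/rate spacing.
3. **Artifact interpolation** over user-specified [start, stop)
   regions: samples are replaced by the straight line joining the
   boundary samples.
4. **Low-pass filtering** at 2 Hz, 4th-order Butterworth applied
   forward–backward (zero phase). The filter is specified by response,
   not coefficients: a 0.1-Hz sinusoid passes within 5 %, a 20-Hz
   sinusoid is attenuated by ≥ 90 %.
5. **Photobleaching correction**: least-squares fit of
   a·exp(−t/τ) + c, subtracted. The offset c makes a constant trace
   the degenerate a→0 case, which maps to ~0.
6. **Motion correction**: the reference is regressed onto the signal
   with a polynomial (default degree 1) and the fitted reference is
   subtracted. This removes components shared by both channels
   (movement, hemodynamics) while leaving calcium transients, which
   the isosbestic channel does not carry. A flat reference is an
   error, not a no-op.
7. **Rolling z-score**: z = (f − f0)/f1 with f0, f1 the mean and
   sample standard deviation in a 60-s window centered on each sample
   (truncated at the edges; the centered/trailing choice is not
   dictated by the quantity's definition, and centered windows avoid a
   systematic lag). A zero-variance window is an error.

Both channels pass through steps 1–5; step 6 consumes them jointly.

**Epoch statistics.** The per-epoch "AUC" is the mean z over the
half-open epoch [start, stop) — a normalized average, not a time
integral. **Event-triggered statistics**: snippets spanning −5..+5 s
around behavior-initiation onsets are aligned and averaged; baseline =
mean over −5..−3 s; the corrected extremum is the maximum (activation
analyses) or minimum (suppression analyses) over 0..3 s minus the
baseline. Onsets too close to the trace edge are dropped with a
warning; polarity is the caller's choice per analysis.

## Behavioral-state classification

All rules operate on the Gaussian-smoothed instantaneous velocity
(positions smoothed with a kernel whose ±3σ support spans 1 s, i.e.
σ = 1/6 s) and on the tracker's per-frame body-motion percentage.
Intervals are half-open [start, stop) in seconds; frames are
half-open, so zone times partition the session duration exactly.

- **Immobility**: speed < 6 cm/s AND motion < 1 %, maximal runs
  strictly longer than 15 frames.
- **Locomotion**: speed > 6 cm/s; a continuous supra-threshold run is
  one bout; runs with path length < 10 cm are discarded. Distance is
  summed over surviving bouts.
- **Pauses** (hole-board): speed < 3 cm/s for ≥ 1 s; locomotion
  initiations are aligned at pause termination.
- **Thigmotaxis zone**: the peripheral 25 % of the arena's linear
  extent (a band of 12.5 % of the side length at each wall); a
  `zone_mode: area` option instead sizes the band so the periphery is
  25 % of the arena area.
- **Focused exploration**: head-dips chained when the end-to-start gap
  to the next dip is ≤ 5 s, merged transitively; chains of ≥ 2 dips
  become episodes spanning first-dip start to last-dip end, singletons
  stay isolated dips. Every dip lands in exactly one category.
- **Ethogram**: frame-wise precedence manual grooming/rearing >
  immobility > locomotion > surveying; surveying is the residual state
  (in place, moving, neither immobile nor locomoting). Frames at
  exactly 6 cm/s satisfy neither strict inequality and fall to
  surveying.
- **Epoch metrics**: consecutive 3-min blocks labeled by the
  Pre/ON/OFF design; repetitions of a label are averaged and the
  averaged table is normalized to Pre by subtraction (a ratio mode is
  available; subtraction is the default because it is defined for
  zero-valued Pre baselines).

## Unit-responsiveness classification

Per unit: firing rate in 100-ms bins around each stimulus, z-scored
against the mean/sd of that unit's pre-stimulus bins pooled across
trials, then averaged across trials (PSTH). Units whose 1-s pre-trial
baseline rate varies by more than 5× across the six burst trials (or
has a zero-rate trial among active ones) are discarded as unstable.
For the rest, the per-trial rate change is the rate in the response
window (burst onset to last-pulse offset + 100 ms; the pad and the
1-s pre-window are configurable, as no canonical values exist) minus
the rate in the preceding 1 s. The six changes are tested against
zero with a one-sample t-test; p-values are Benjamini–Hochberg
adjusted across units; adjusted p < 0.05 with negative (positive)
mean change yields "inhibited" ("excited"), else "nonresponsive". A
zero-variance set of changes gets p = 0 if the mean is nonzero and
p = 1 otherwise, so deterministic batch runs never crash on undefined
statistics. Inhibition latency is the first post-stimulus bin of the
trial-averaged PSTH below −1.0 z (≈2.5 null standard deviations of a
6-trial mean).

## Puncta colocalization

A cell is SYP+ or vGLUT2+ when it carries ≥ 4 puncta of the channel
(thresholds independent and configurable per channel). The two
conditional fractions — P(vGLUT2+ | SYP+) and P(SYP+ | vGLUT2+) — use
set semantics (double positives count in both denominators); an empty
denominator returns an explicit `Undefined(reason)` sentinel rather
than raising, since sparse sections legitimately produce empty
classes. `count_validation` summarizes automated-vs-manual nucleus
counts as mean ± sd of the per-image overcount and percent overcount.

## Synthetic-data generators

Every generator is deterministic in (config, seed) and ships its
ground truth, so recovery tests need no re-derivation.

**Photometry.** signal = baseline·exp(−t/τ) + shared artifact +
event-locked transients + white noise; reference = its own exponential
baseline + the same artifact at gain 0.8 + independent noise, no
transients. Defaults: 10-min sessions, 100 Hz, bleach τ = 300 s, 20
events, transient amplitude 2.0 z, double-exponential kernel (0.2-s
rise, 1.5-s decay, a slow-indicator shape whose peak sits inside the
0–3-s extremum window). The artifact amplitude defaults to 60× the
post-low-pass noise sd (≈10 % of baseline fluorescence): motion
artifacts in freely moving animals dwarf the shot-noise floor, and
this also puts the reference channel in the artifact-dominated regime
the polynomial-fit subtraction assumes. Transient amplitude is
specified in z units; the generator calibrates the raw amplitude by
passing the transient-free composition through the same
low-pass/bleach/reference-subtraction chain, measuring the residual
floor, and compensating the kernel's own low-pass attenuation.
Artifacts are placed midway between event onsets so the two recovery
measurements do not interact. Residual ~4 % negative bias in
amplitude recovery remains because transients themselves inflate the
60-s rolling sd.

**Tracking.** Trajectories realize scripted bout sequences in the
arena: immobility holds position (motion 0.2 %), wall-following moves
along a rectangle just inside the walls, center runs approach and then
orbit a circle at 25 % of the arena side — both at exactly the
scripted speed, so threshold crossings are sharp. The motion column is
scripted consistently with speed (0.2 % still, 3 % surveying, 8 %
moving). The default script alternates 20 s immobility / 20 s
wall-following / 10 s immobility / 20 s center locomotion for 13
cycles (910 s), covering a five-epoch Pre/ON/OFF design.

**Spike trains.** Homogeneous Poisson units at rates drawn uniformly
from 2.2–31.8 Hz (the observed tonic range), over a 1-min baseline,
6 single 10-ms pulses and 6 five-pulse 10-Hz bursts at 5-s intervals.
Responders are thinned by (1 − inhibition_depth) from 20 ms after
each stimulus onset until 100 ms past its offset. Thinning a
homogeneous train keeps generation exact and seedable.

**Puncta.** Positive cells draw threshold + Poisson(4) puncta,
negative cells uniform 0..3; SYP positivity is Bernoulli(p_syp),
vGLUT2 positivity Bernoulli(0.8) given SYP+ and Bernoulli(0.5)
otherwise in the default recovery setting.

### What the generators do and do not emulate

They reproduce the statistical structure the analyses assume —
shared-artifact two-channel photometry, exponential bleaching,
event-locked slow-kernel transients, threshold-separable behavioral
states, tonic Poisson spiking with step inhibition, threshold-split
count distributions. They do not emulate hemodynamic artifacts with
channel-dependent dynamics, indicator nonlinearity or saturation,
tracking jitter and identity switches, bursty or refractory spiking,
or spatial structure in puncta. Passing recovery tests therefore
demonstrates correctness of the implemented rules under their own
assumptions, not robustness of the rules to real-data violations of
those assumptions.

## Problem sizes and numerical choices

Validation runs use 20 photometry sessions of 10 min, one 910-s
trajectory, 1000 null units and 100 repetitions of the 27-unit
design, 1000 random dip schedules and 1000 random puncta tables, and
200 recovery seeds — sizes at which the binomial/simulation error of
each summary is well below the tolerance it is compared to. Sub-seeds
derive from the user seed via `numpy.random.SeedSequence`. Exact-rule
checks (rolling z-score vs the O(n·w) oracle, BH vs the step-up
oracle, fractions vs counting) are held to 1e-10 or exact equality;
stochastic recoveries to their sampling tolerances (10 % amplitude
bias, 0.95 bout Jaccard, binomial interval coverage ≥ 93 %).

## Known limitations

- The bleach model is a single exponential with offset; two-component
  bleaching is available but off by default and unfitted sessions fail
  loudly rather than silently detrending.
- Motion correction is a global polynomial regression; time-varying
  artifact gain would need a sliding fit, out of scope here.
- The rolling z-score's truncated edge windows have higher variance
  than interior windows; event-triggered analyses should keep onsets
  at least half a window from the edges (the generator does).
- With six trials the t-test has limited power for partial inhibition;
  the validated regime is strong silencing, as in the design it
  mirrors.
- Group-level aggregation across animals (and its hypothesis tests)
  is deliberately left to standard statistical tooling on the exported
  per-session summaries.
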