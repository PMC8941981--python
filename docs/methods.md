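# Methods

`betarec` models a two-experiment program: electrophysiological
characterization of encoding-related beta-band dynamics in dorsolateral
prefrontal cortex (dlPFC), and a causal test of those dynamics with
repetitive transcranial magnetic stimulation (rTMS) during the encoding
phase of a recognition-memory task. Because neither the recordings nor the
participant data are public, every analysis stage is paired with a
generative model of the data it consumes; the statements the test suite
can make are therefore statements about the *procedures* — calibration,
recovery, arithmetic — not about any particular animal or participant.

## 1. Electrophysiology arm

### Signal model

Each synthetic trial is a single-channel LFP epoch spanning −1000 to
+1000 ms around sample onset (1 kHz by default; a 30-kHz mode exists only
to exercise the decimator), plus a separate 1000-ms intertrial baseline:

    x(t) = n(t) + burst(t),

where `n(t)` is spectrally shaped Gaussian noise with power ∝ 1/f^γ
(γ = 1 by default, unit variance, optional 50/100/150-Hz line components)
and `burst(t)` is a narrow-band transient: carrier drawn uniformly in the
band (10–15 Hz default), envelope zero before onset, linear rise to the
peak latency (100 ms default), exponential decay afterwards. Hit and miss
trials differ only in amplitude (2.0 vs 1.0) and decay constant (120 vs
300 ms): hits carry a larger, faster-collapsing burst. Baselines contain
noise only. These four numbers are the study conditions every downstream
calibration uses; they were chosen to produce an effect that is obvious at
a few hundred trials (the scale of the recorded data sets, 346/118
hit/miss) without being detectable from single trials.

### Processing chain

1. **Notch + decimation** (`spectral.preprocess`): second-order IIR notch
   at 50/100/150 Hz (quality factor 30, forward–backward so phase-neutral),
   then polyphase anti-aliased resampling to 1 kHz. Q = 30 is a
   conventional choice; the attenuation contract the tests enforce is
   ≥ 20 dB at the notch and ≤ 1 dB in the passband.
2. **Baseline-RMS normalization** (`spectral.baseline_normalize`): each
   epoch divided by the root-mean-square of its own intertrial baseline;
   power downstream is in baseline-RMS units.
3. **Morlet decomposition** (`spectral.morlet_tfr`): complex Morlet
   wavelets, 7 cycles at every frequency (configurable; the unit tests run
   at 5 and 7), on an integer grid of 8–60 Hz (53 frequencies). The
   wavelet gain is scaled so that a sine of amplitude *a* yields power
   ≈ *a*²at its frequency. Samples within half a wavelet of either epoch
   edge are flagged invalid rather than padded — this is why 1000-ms
   epochs shrink to 800-ms analysis windows.
4. **Permutation test** (`permtest.permutation_test`): statistic = per-cell
   median power over post-onset segments minus median over pre-onset
   segments. On each of 10,000 permutations (1000 in the reduced
   calibration studies) segments are relabelled — pooled shuffle by
   default, within-trial pre/post swap as the paired alternative — and the
   *global* maximum and minimum of the permuted map are recorded. The
   upper/lower thresholds are the 97.5th percentile of the maxima and the
   2.5th percentile of the minima; any observed cell outside them is
   significant at the two-tailed .05 level. Using the global extrema
   (max-statistic control) bounds the family-wise error; a `matrixwise`
   option keeps per-cell extrema instead, for comparison with a literal
   per-cell reading of the thresholding, and is anticonservative.
5. **Band dynamics** (`band_dynamics`): the band of significant post-onset
   increase is extracted per subject, bands are intersected across
   subjects, and the stimulation frequency is the midpoint of the
   intersection (10–17 ∩ 8–15 → 10–15 → 12.5 Hz). Within the common band,
   per-frequency post-peak slopes are ordinary least squares on the
   trial-averaged power over a 150-ms window starting at the detected band
   peak (fixed windows accepted via config), and hit vs miss slopes are
   compared with a paired t test across the 6 in-band frequencies (df = 5).

### What the calibrations show — and a known failure

The family-wise error study (`pipeline.null_fwer_study`) generates
burst-free datasets, so pre- and post-onset segments are exchangeable by
construction, and runs the full chain on a reduced grid (10 frequencies ×
100 time points, 20 trials, 1000 permutations). Epochs are generated at
±1600 ms so that both 800-ms windows lie wholly inside the wavelet-valid
region; without that margin the pre and post windows would have mirrored
edge-variance profiles and exchangeability would fail at the window ends.
Measured family-wise error is ≈ 0.05, as max-statistic control predicts.

The paired t over per-frequency gradients does *not* calibrate, and this
is a property of the design, not a bug in the code: with 7-cycle wavelets
the spectral resolution is σ_f ≈ f/7 ≈ 1.7 Hz at 12 Hz, so slopes at
1-Hz-spaced frequencies are strongly correlated (neighbor correlation
≈ 0.8, roughly 3–4 effectively independent frequencies out of 6). Treating
the 6 slopes as independent pairs inflates the t statistic; under a fully
label-exchangeable generator the measured rejection rate is ≈ 0.4 at
nominal .05, regardless of trial count (the inflation is scale-invariant)
and of whether the fit window is detected or fixed. The test suite states
this expectation honestly: the power property (hit-faster-decay detected
in ≥ 90% of replicates) holds, the nominal-level calibration property
does not. Conclusions drawn from this statistic should treat its p-values
as descriptive.

## 2. Behavioral arm

### Design generator

`task_design.build_session` reproduces the session structure: 3
subsessions × 15 blocks × (12 samples + 12 test trials) = 540 test trials;
each block is beta-, random- or no-stimulation, 5 of each per subsession in
random order; 6 match + 6 nonmatch test trials per block, match stimuli
drawn from the block's sample list, nonmatch stimuli novel, all stimulus
ids session-unique. In stimulated blocks 4 of the 12 samples are targeted,
with ≥ 2 non-targeted samples between consecutive targets; the schedule is
drawn uniformly from the 15 admissible configurations (exhaustively
enumerated, as is the 462-element set of 6-of-16 non-adjacent pulse-bin
subsets for random trains). Beta trains are 6 pulses every 80 ms from
sample onset (12.5 Hz); random trains place 6 pulses at the starts of
non-adjacent 30-ms bins. The "two non-stimulated in between" constraint is
applied only between targeted positions, not at the list edges, matching
its wording. By default the number of match-test trials probing targeted
samples is emergent (≈ 30 per stimulated condition per session); the
pipeline's cohort studies force the published per-session totals
(36 beta / 33 random) via `force_targeted_match`, since the fixed stimulus
order that produced them is not public.

### Response model

Responses follow the dual-process signal-detection (DPSD) generative
model. On a match trial the item is recollected with probability R_eff and
answered *absolutely certain old* (level 1; a config option spreads
recollected responses over levels 1–2); otherwise a familiarity strength
~ Normal(d′_eff, 1) is binned by five ordered criteria into levels 1–6,
with "old" ⇔ level ≤ 3 (the decision is tied to the middle criterion, so
decision and rating come from one strength draw). Nonmatch trials draw
strength from Normal(0, 1). Defaults: R = 0.3, d′ = 1.2, criteria
(1.2, 0.6, 0, −0.6, −1.2), lapse 0. rTMS effects are recollection
decrements on targeted match trials (δ_R = 0.15 under beta at dlPFC in the
effect studies; 0 for random, vertex, and familiarity), with an optional
spillover fraction onto untargeted same-block trials (default 0).
Cohort-level heterogeneity: R_base ~ N(0.3, 0.05) clipped to [0,1],
d′ ~ N(1.2, 0.15) across participants.

### ROC and DPSD fitting

`roc_dpsd.build_roc` cumulates from the most-confident-old level outward:
point *i* = (P(lure level ≤ i), P(target level ≤ i)) for i = 1..5; the
sixth point is (1,1) by construction and excluded. (The source procedure's
prose enumerates the scale from the *new* end while calling level 6
"absolutely certain new"; the model equations accumulate "old" responses,
so the old-first direction is used, with a flag to reverse.) The model
predicts p_fa = Φ(−c), p_hit = R + (1−R)Φ(F−c) with the lure threshold
fixed at 0 and unit familiarity SD. Fitting minimizes the summed squared
residuals of both coordinates over (R, F, c₁..c₅) with
`scipy.optimize.least_squares` (trust-region reflective, analytic
Jacobian), criteria kept ordered by a base-plus-negative-increments
reparameterization, and three starting points (criteria initialized from
the probit of the observed false-alarm rates). A relaxed first pass allows
R ∈ [−1, 1]; a negative optimum fixes R = 0 and refits (negative
recollection is meaningless), flagged as `refit_applied`. F is bounded
below at 0. Observed rates of exactly 0 or 1 enter as-is — the objective
is least squares, not likelihood, so no corrections are needed. A 12-start
audit on 150 noisy ROCs found no start-dependence of the optimum.

Noise-free self-consistency recovers (R, F) to < 10⁻³ across a 3 × 3 truth
grid; under sampling noise at 5000 + 5000 trials the mean of 100 fits is
within 0.03 / 0.08 of (0.3, 1.2). At realistic per-stratum sizes
(36 targets / 90 lures) single fits are noisy — sd(R̂) ≈ 0.2, with an
upward clipping bias ≈ +0.03 when true R = 0.15 — which materially limits
what a 9-participant cohort can show (see below).

### Indices

`behavior_analysis.within_block_indices` fits, per participant and
stimulated condition, the targeted (+) and untargeted (−) match strata,
both against all of that condition's nonmatch trials (nonmatch trials have
no targeted identity; restricting the lure set is configurable).
`between_block_indices` compares conditions using targeted match trials
for beta and random and all match trials for no-stimulation, each against
that condition's own lures. `hit_rate` is hits / match trials within a
stratum; nonmatch trials never enter. Group-level ANOVAs are deliberately
not implemented: `index_table` exports the tidy long table
(participant × site × condition × stratum with R, F, hit rate, counts) for
any standard statistics package; the only inferential statistic shipped is
the paired t shared with the LFP arm.

### What the cohort replication shows

With the fixed conditions (9 dlPFC participants, δ_R = 0.15 under beta,
36/33 targeted-match trials, separate least-squares fits per stratum), the
cohort mean R̂+ falls below R̂− under beta stimulation in ≈ 83–90% of
replicates — the observable gap is attenuated to ≈ −0.11 by the clipping
bias, and the cohort SE is ≈ 0.08, so single cohorts miss the effect with
noticeable probability. Random-stimulation R gaps and all F gaps sit at
chance. This quantifies a real design limit of 36-trial ROC strata rather
than a property of the fitted model.

## 3. Reproducibility

All randomness flows through `numpy.random.Generator`. Pipeline stages
draw from independent streams seeded by (global seed, stage name), so a
stage can be rerun in isolation with the stream it saw in the full run.
Run directories contain `report.json` and `run_log.json` with the seed, a
config hash and the full parameter echo; identical seeds give
byte-identical reports.

## 4. Problem sizes used by the shipped studies

- Family-wise error: 200 datasets × 20 trials, 10 × 100 grid, 1000
  permutations.
- Gradient power/calibration: 50 replicates × (346 hit + 118 miss) trials.
- DPSD recovery: 100 participants × (5000 + 5000) trials.
- Cohort replication: 200 cohorts × 9 participants × 540 trials.

These are the scales at which the statistical claims in the test suite
were computed; the full-grid, 10,000-permutation configuration is the
default for pipeline runs but not exercised by the studies above.

## 5. Known limitations

- The synthetic LFP has a single deterministic-envelope burst per trial;
  real recordings have trial-varying latency and multi-channel structure
  (channels can be stacked as independent trials or analyzed per channel,
  but no cross-channel model is provided).
- The generative behavioral model is exactly the fitted model (plus
  optional lapse); passing recovery tests therefore shows estimator
  correctness, not robustness to misspecification.
- The per-frequency gradient t test is anticonservative by construction
  (correlated frequencies); see above.
- The two-stage response (touch, then rate) is collapsed into a single
  strength draw; response times are not modelled.
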