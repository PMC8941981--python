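# betarec

Analysis pipeline for encoding-related beta-band LFP dynamics and their
causal test with rTMS in a recognition-memory task — with synthetic-data
generators standing in for the (non-public) recordings and participant
data, so every stage is runnable and testable end to end.

## Who this is for

Two audiences: electrophysiologists who need a calibrated, family-wise
error-controlled way to ask *where in frequency–time does post-stimulus
LFP power differ from baseline*, and memory researchers who need
confidence-rating ROC construction plus dual-process signal-detection
(DPSD) model fitting for recognition data with stimulated vs
non-stimulated strata.

## What it computes

**Electrophysiology arm.** LFP trial epochs are notch-filtered, decimated
to 1 kHz, divided by their intertrial-baseline RMS, and decomposed with
complex Morlet wavelets (8–60 Hz, 1-Hz steps). Pre- vs post-onset power is
tested per frequency–time cell with a nonparametric permutation test using
the median difference as statistic and the permutation distribution of the
map's global maximum/minimum as the two-tailed reference — any observed
cell above the 97.5th percentile of the maxima or below the 2.5th
percentile of the minima is significant at .05 with family-wise error
control. The band of significant post-onset increase is intersected across
subjects and its midpoint becomes the stimulation frequency; post-peak
band dynamics are summarized by per-frequency OLS gradients over a 150-ms
window, compared between hit and miss trials with a paired t test
(df = number of in-band frequencies − 1).

**Behavioral arm.** A session generator reproduces the task structure
(3 subsessions × 15 blocks × 12 samples + 12 test trials; beta / random /
no-stimulation blocks; 4 of 12 samples targeted with ≥ 2 untargeted in
between; 6-pulse trains — every 80 ms for beta, i.e. 12.5 Hz, or in
non-adjacent 30-ms bins for random). Responses on a 6-point
confidence scale (1 = *absolutely certain old* … 6 = *absolutely certain
new*) are cumulated into 5-point ROCs, and the DPSD model

    p_fa(c_i)  = Φ(−c_i)
    p_hit(c_i) = R + (1 − R) · Φ(d′_F − c_i)

is fit by least squares over both coordinates (R ∈ [0,1] recollection,
d′_F ≥ 0 familiarity, ordered criteria; a negative best-fit R is fixed to
0 and the model refit). Within-block indices (R+, R−, F+, F−) contrast
targeted vs untargeted match trials; between-block indices compare the
three stimulation conditions; a tidy index table is exported for external
ANOVA.

## Worked example

```python
from betarec.pipeline import RunConfig, SubjectLFP, run_lfp_arm

cfg = RunConfig(seed=7, n_perm=500, freqs_hi=30.0,
                subjects=(SubjectLFP("A", n_hit=60, n_miss=30, band=(10.0, 17.0)),
                          SubjectLFP("B", n_hit=60, n_miss=30, band=(8.0, 15.0))))
report = run_lfp_arm(cfg)
for name, sub in report["subjects"].items():
    t = sub["band_summary"]["paired_t"]
    print(f"subject {name}: sig band {sub['hit']['sig_band']}, "
          f"mean slope hit {sub['band_summary']['mean_slope']['hit']:.2e}, "
          f"miss {sub['band_summary']['mean_slope']['miss']:.2e}, "
          f"t({t['df']}) = {t['t']:.2f}, p = {t['p']:.4f}")
print("common band:", report["common_band"], "-> stimulation frequency:",
      report["stim_frequency_hz"], "Hz")
```

prints

```
subject A: sig band (11.0, 18.0), mean slope hit -3.39e-03, miss -9.35e-04, t(5) = -5.55, p = 0.0026
subject B: sig band (10.0, 15.0), mean slope hit -3.02e-03, miss -6.11e-04, t(5) = -7.33, p = 0.0007
common band: (11.0, 15.0) -> stimulation frequency: 13.0 Hz
```

Reading this: in both simulated subjects the permutation test flags a
low-beta band whose power rises after sample onset on hit trials (the
generators injected 10–17 and 8–15 Hz bursts; the detected bands are
smeared by ~1 Hz of wavelet bandwidth). Post-peak power collapses roughly
3–5× faster on hit than miss trials, the paired t over the in-band
per-frequency gradients is strongly negative with df = 5, and the
band intersection picks a stimulation frequency in the low-beta range.

The behavioral arm runs the same way (`run_behavior_arm(cfg)`), or from
the shell:

```bash
betarec design --seed 1 --out session.json
betarec simulate-behavior --seed 1 --out responses.csv
betarec analyze-behavior --responses responses.csv --out indices.csv
betarec run-lfp-arm --seed 1 --out lfp_run/
```

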