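# rhythmgain

Simulation and analysis of how **rhythmic temporal expectation** modulates
auditory processing in multichannel M/EEG.

When sounds arrive in a regular rhythm, listeners can predict *when* the
next relevant event will occur, and both behavioral discrimination and the
neural representation of sounds improve around the expected moment.  A
central question is whether this improvement reflects a nonspecific
**gain** increase (all frequencies are represented better) or a
**sharpening of frequency tuning** (only task-relevant frequencies
benefit).  `rhythmgain` implements, end to end, the analysis chain used to
answer this question with multivariate decoding — and, because raw
recordings of this kind are rarely shared, pairs it with a synthetic-data
generator with known ground truth so that every stage of the chain can be
validated by parameter recovery.

The package is aimed at researchers in auditory cognitive neuroscience and
M/EEG methods who want a tested reference implementation of
Mahalanobis-distance decoding, phase-locking analysis and population
gain/tuning modelling, or a sandbox in which to probe the power and
specificity of these methods under controlled conditions.

## What it implements

**Paradigm** (`stimgen`): gapless sequences of brief pure tones (15
log-spaced carriers spanning two octaves, 460–1840 Hz; durations 23–43 ms)
interleaved with six-tone chords of two identities (A/B) that share member
frequencies but differ in the amplitudes of four discriminant tones.
Chords repeat at a 1 s inter-stimulus interval (rhythmic blocks) or with
jittered timing (jittered blocks; half the intervals stay at 1 s so that
analysed events are physically matched).  20% of chords are long targets
that listeners must categorise; a 1-up-2-down adaptive staircase titrates
the discriminant amplitude difference to ≈70% accuracy.

**Forward model** (`synthmeeg`): sensor arrays with EEG-, magnetometer-
and gradiometer-like channel families; tone-evoked responses whose
amplitude varies linearly with frequency rank; chord-identity
topographies; a 1 Hz component phase-locked to chords only in rhythmic
blocks (equal power in both conditions); a configurable multiplicative
gain on tone responses in a window of lags before the expected chord; and
spatially correlated noise.

**Analysis** (`preprocess`, `encoding`, `spectral`, `decoding`,
`tuningmodel`, `statkit`, `behavior`, `pipeline`):

* zero-phase Butterworth filtering, average-reference EEG, epoching,
  moving-average smoothing, and SVD dimensionality reduction per channel
  family;
* mass-univariate Spearman correlation between evoked amplitude and tone
  frequency (monotonic and quadratic contrasts);
* phase-locking value (PLV) and power in the 0.5–5 Hz range from a
  fixed-window (2000 ms) complex-sinusoid transform;
* leave-one-out **Mahalanobis-distance decoding** of tone frequency with a
  Ledoit–Wolf shrinkage covariance: for every lag relative to chord onset,
  a 15 × 15 distance matrix is built from held-out trials (minimum distance
  over a 26–126 ms response window per reference band) and scored by
  Spearman correlation against the ideal matrix of carrier-frequency
  differences; the same scheme decodes chord identity;
* a three-parameter population **gain/tuning model**
  `Z(Δf) = c + g·exp(−Δf²/2σ²)` fitted to distance profiles by robust
  IRLS, compared over a 7-model space by AIC and random-effects Bayesian
  model selection (a more negative gain `g` means better decoding at all
  frequency separations; a smaller `σ` means sharper tuning);
* cluster-based sign-flip permutation tests (1-D and channel ×
  time–frequency), a 2 × 4 repeated-measures ANOVA, paired t tests, and
  Pearson correlation with Cook's-distance influence screening;
* signal-detection behavioral summaries (accuracy, d′, criterion, RT
  filtering).

## Worked example

Simulate and analyse one desk-scale virtual participant (3 rhythmic and 6
jittered blocks of 12 trials) with the default ground truth, which injects
a rhythmic-only gain boost at lags −100 to −80 ms before chord onset:

```python
import numpy as np
import rhythmgain as rg

cfg = rg.RunConfig(master_seed=0, n_rhythmic_blocks=3, n_jittered_blocks=6)
s = rg.run_subject(cfg, 0)

diff = s.score_series["rhythmic"] - s.score_series["jittered"]
sel = (s.lags_ms >= -100) & (s.lags_ms <= -80)
print("peak benefit lag (ms):", int(s.lags_ms[np.nanargmax(diff)]))
print("rho rhythmic in [-100,-80]:", round(float(np.nanmean(s.score_series["rhythmic"][sel])), 3))
print("rho jittered in [-100,-80]:", round(float(np.nanmean(s.score_series["jittered"][sel])), 3))
print("gain g rhythmic:", round(s.tuning_fits["rhythmic"].g, 3),
      " jittered:", round(s.tuning_fits["jittered"].g, 3))
```

Output:

```
peak benefit lag (ms): -100
rho rhythmic in [-100,-80]: 0.668
rho jittered in [-100,-80]: 0.339
gain g rhythmic: -1.083  jittered: -0.529
```

The decoding benefit of rhythmic timing peaks inside the injected gain
window; tone frequency is decoded better (higher correlation with the
ideal distance matrix) just before the expected chord, and the gain/tuning
model attributes this to a more negative gain parameter in the rhythmic
condition — the population-level signature of a nonspecific gain increase.
The same subject's 1 Hz phase locking at chord onset is 0.83 in the
rhythmic versus 0.26 in the jittered condition, and behavioral accuracy is
75.8% versus 66.7%.

`rg.run_experiment(cfg)` runs many virtual subjects and adds the group
inference: cluster permutation tests of every condition contrast, Bayesian
model selection over the gain/tuning model space, the frequency-class
ANOVA, and cross-measure correlations.  A thin CLI is available as
`rhythmgain run --config cfg.yaml --out results/` and
`rhythmgain simulate ...` for writing recordings to HDF5.

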