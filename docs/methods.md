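# Methods

This note documents the models, estimators and design choices behind
`rhythmgain`: what the synthetic data contain, how each analysis stage is
defined, which defaults matter, and what the passing tests do and do not
establish about real recordings.

## Stimulus design

Pure tones draw carriers from a 15-band grid, log-spaced over two octaves
(460–1840 Hz), and durations from {23, 28, 33, 38, 43} ms.  Tones tile
every interval between chords without gaps; the last tone before a chord
is truncated so the tiling closes exactly (a design choice: "gapless"
is enforced at 1 ms resolution).  Chords contain six member bands: two
common bands with equal amplitude in both identities and four
discriminant bands split into a pair louder in chord A and a pair louder
in chord B, with the constraint that neither pair lies entirely above or
below the other on the frequency axis.  Common-tone amplitude defaults to
the mean of the two discriminant levels and is exposed as a parameter
(`ChordSpec.common_amplitude`), since nothing pins it down uniquely.
Remaining bands are classed `adjacent` (grid neighbours of a discriminant
band) or `distant`.

Each trial is a 1 s tone lead-in, three to five short chords, a 165 ms
target chord, and a 700 ms tone tail.  Rhythmic blocks use a constant 1 s
chord ISI.  Jittered blocks enforce the proportions exactly per block by
shuffled assignment — ⌊m/4⌋ intervals in 570–908 ms, ⌊m/4⌋ in
1092–1430 ms, the remainder at 1 s — rather than by independent coin
flips, because the proportions are design facts, not random rates.  The
first chord of a trial has no preceding interval (its `preceding_isi_ms`
is NaN), which automatically excludes it from every "preceded by 1 s"
selection; the target has no following interval and is likewise excluded
from the phase-locking selection.

The staircase (`staircase_calibrate`) is 1-up-2-down with a step size
halved at each reversal down to a floor of 1% amplitude, converging on
the level where p(correct)² = 0.5, i.e. ≈70.7% accuracy.  The returned
level is the mean of the final reversals (up to 60, trimmed to an even
count so staircase peaks and troughs balance).  A single 400-trial run
estimates the converged accuracy with a standard deviation of roughly 3
percentage points; the acceptance script therefore averages replicate
staircases when reporting the asymptotic accuracy.

Rendered audio tapers every stimulus with 5 ms Hanning flanks and scales
each stimulus to a common RMS over its duration.  This is a deliberate
simplification of time-varying-loudness normalisation, which cannot be
reproduced without the underlying loudness-model tables; equal RMS
preserves the testable invariant (constant level across stimuli).

## Synthetic recordings

Sensors lie on a jittered Fibonacci spiral over a spherical cap, which
emulates the quasi-regular spacing of real arrays and guarantees that the
default adjacency rule (neighbours within 1.3 × median nearest-neighbour
distance) leaves no channel isolated.  Channel families (EEG-like,
magnetometer-like, gradiometer-like) are interleaved over the cap and
share arbitrary units; the default desk-scale array is 14 + 14 + 20
channels (configurable; the full-size system would be 60 + 102 + 204).

The forward model is a sum of:

* **Tone responses** — a unit-peak Gaussian kernel (latency 76 ms, width
  12 ms, matching early auditory evoked components) times a topography
  `tone_amp · base + slope · (rank − 7) · mod`, where `base` and `mod` are
  fixed unit-norm random patterns.  The code is linear in frequency rank,
  i.e. purely monotonic — matching the empirical finding that quadratic
  frequency contrasts add nothing — with default slope 0.25 a.u./rank.
* **Gain envelope** — each tone response is multiplied by
  `1 + gain_boost` when the tone's temporal midpoint falls inside
  `gain_window_ms` (default −100 to −80 ms) relative to the next chord
  onset, in the boosted condition only (default rhythmic).  Evaluating the
  envelope at the tone midpoint centres the recoverable effect on the
  injected window; evaluating at tone onset would skew it late by half a
  tone duration.  The default boost of 5 (a 6× response gain inside the
  20 ms window) is chosen so that a *single* desk-scale virtual subject
  recovers the injected window reliably; at full scale the group-level
  cluster statistics would supply the averaging that desk-scale runs lack.
  The resulting decoding contrast (ρ ≈ 0.3–0.7 rhythmic vs ≈ 0.1–0.3
  jittered in the boosted window) brackets the kind of threefold contrast
  the method is meant to detect, while baseline (unboosted) scores stay in
  a realistic ρ ≈ 0.05–0.2 range.
* **Chord responses** — a common topography plus an identity-specific
  pattern, kernel latency 125 ms (so the chord-decoding effect lands in
  the 115–136 ms analysis window).
* **Entrainment** — a 1 Hz sinusoid spanning each trial with amplitude
  `entrain_strength[condition]` (default 0.8 in both conditions), phase
  locked to chord onsets in rhythmic blocks and randomly phased per trial
  in jittered blocks.  Both conditions therefore carry equal 1 Hz power;
  only the across-trial phase consistency differs, which is exactly the
  PLV-without-power signature the analysis is designed to detect.
* **Noise** — temporally white Gaussian noise (sd 1.0) mixed by a random
  full-rank matrix with unit row norms, giving spatially correlated
  sensor noise of the nominal variance.  1/f-shaped noise is available
  (`pink_noise=True`) but off by default for speed.

Behavior is Bernoulli per target at the condition's accuracy (defaults
0.72 rhythmic / 0.69 jittered, the size of effect the paradigm produces)
with lognormal RTs (median 715 ms, σ = 0.2).

What the generator does **not** emulate: head geometry and field spread,
blink/cardiac artifacts, non-stationary noise, frequency-dependent
response latencies, or any coupling between the entrained oscillation and
response gain (gain is injected directly).  Passing recovery tests
therefore show that the *analysis chain* is correct and well calibrated —
not that real cortical dynamics behave this way.

## Preprocessing

Continuous data are filtered with fifth-order Butterworth designs applied
forward-backward (zero phase; effective order doubles): high-pass
0.1 Hz, band-stop notches at 50 Hz and harmonics up to the low-pass
corner, low-pass 200 Hz.  The cascade runs in single precision
internally — the near-DC high-pass otherwise spends most of its time in
denormal arithmetic — which is far below the simulated noise floor.  EEG
channels are re-referenced to their instantaneous average; MEG families
are untouched.  Epoch smoothing is a centred 20 ms moving average with a
truncated (shrinking) window at the epoch edges, preserving length
without padding artifacts.

Dimensionality reduction follows the correlation-map route: the
grand-average tone-evoked per-band amplitudes are correlated with the
monotonic frequency contrast per channel and time point, and each channel
family's correlation map is decomposed by SVD.  By default the pipeline
keeps a **fixed** number of modes per family (6 at desk scale) rather
than the smallest count reaching 95% variance: subject-specific mode
counts would make component spaces incomparable when stacking subjects in
group maps.  `compute_component_basis` supports both rules
(`var_target`/`max_modes` vs `exact_modes`) and records the retained
variance either way.  Mode signs follow a fixed convention (largest
weight positive), so projections are reproducible.  Whether single-trial
decoding inputs should pass through this correlation-map basis or a
separate continuous-data SVD is genuinely ambiguous; the correlation-map
basis is the default and the alternative is a caller-side substitution.

## Decoding

Trials are the short chords preceded by a 1 s interval (so the
stimulation before every analysed event is identical across conditions).
For each lag on a −500…+500 ms grid, the tone "active" at that lag is the
one whose onset–offset span contains it (tones are gapless, so this is
unique; lags inside the chord itself have no tone and are flagged
missing).  Features are single-trial component amplitudes at response
offsets 26–126 ms after the lag (step 5 ms at full scale, 20 ms at desk
scale).  The pipeline applies the same 20 ms moving average to the
component time series before decoding; smoothing the decoding inputs
substantially stabilises the windowed-minimum statistic.

For each held-out trial, Mahalanobis distances to the 15 per-band mean
patterns use class means and a Ledoit–Wolf shrinkage covariance (toward a
scaled identity, analytic intensity) computed from all *other* trials.
The leave-one-out family of shrinkage covariances is evaluated in closed
form, vectorised over folds — algebraically identical to refitting per
fold (tested against the direct estimator).  The per-band minimum across
response offsets accommodates latency variability and is taken
independently per reference band; ties resolve to the earliest offset via
`nanmin`.  Held-out distances are averaged by presented band into a
15 × 15 matrix per lag; bands absent from a fold's training set yield NaN
cells, which scoring pairwise-deletes.  The decoding score is the
Spearman correlation with the ideal matrix of absolute carrier-frequency
differences; a constant observed matrix scores 0 by convention (flagged
degenerate) so group pipelines stay total.

Chord decoding reuses the identical scheme with two classes over
peri-chord time points −100…+400 ms, reporting the relative distance
(other-identity minus same-identity); positive values indicate
discriminable chord representations.

## Phase locking

Instantaneous phase and power use a fixed-duration analysis window: a
2000 ms Hanning-tapered complex sinusoid per frequency (0.5–5 Hz, 0.1 Hz
steps at full scale) and time point (−500…+500 ms, 50 ms steps),
giving frequency-independent temporal resolution (a constant-cycle
wavelet would contradict the fixed-window definition; a Gaussian taper is
available).  PLV is the magnitude of the across-trial mean unit phasor.
Only chords preceded *and* followed by 1 s intervals enter.  Because PLV
is positively biased by ≈ `0.5·sqrt(pi/N)` under uniform phases, the
pipeline randomly subsamples both conditions to the common trial count
before computing PLV/power maps — otherwise the condition *difference*
inherits a systematic bias from unequal selection counts and the null
test becomes anticonservative.  This mirrors, at the trial level, the
sample-equalisation principle built into the 3:6 block design.

## Gain/tuning model

Observed distance matrices (averaged over the analysis lag window,
default −100 to −80 ms) are assumed symmetric about the diagonal and
pooled by absolute band-index difference Δf = |i − j| (the natural axis on
a log-spaced grid, where spacing is uniform in octaves).  The model

    Z(Δf) = c + g · exp(−Δf² / (2σ²))

is fitted by iteratively reweighted least squares with bisquare weights
(tuning constant 4.685, MAD scale, max 200 iterations, convergence at
1e-8 relative parameter change; inner solves via trust-region least
squares).  σ is constrained to [0.3, 8] band-index units: beyond ~8 the
Gaussian flank degenerates into a shallow quadratic and (g, σ) trade off
along a ridge, producing arbitrarily large compensating estimates.  The
exact functional form (normalisation; σ vs σ²) is a declared convention;
all claims rest on self-consistent generate-and-fit recovery, not on
matching any external parameter scale.

The model space holds the full model and the six reduced models in which
every proper subset of {g, σ, c} is free, with fixed parameters anchored
to the grand-average fit.  AIC = n·ln(RSS/n) + 2k (Gaussian residual
approximation; an exact fit returns a −∞ sentinel with a flag), and
−AIC/2 enters random-effects Bayesian model selection: variational
Dirichlet updates of assignment posteriors, with exceedance probabilities
from 10⁵ seeded Dirichlet posterior samples.  Per-condition fits start
from the fit to the subject's condition-averaged matrix so that the two
condition estimates are directly comparable; per-frequency-class fits
(discriminant/adjacent/distant/common rows) feed the 2 × 4
repeated-measures ANOVA.

## Inference

Cluster tests threshold pointwise t statistics at the two-tailed critical
value for p = 0.05 with n − 1 df, form contiguous supra-threshold clusters
(per sign; in the channel × time–frequency variant, 4-connected cells
within a channel plus co-localised cells of adjacent channels), score them
by summed t, and compare against the max-cluster-mass null from sign-flip
permutation of the subject series.  For n ≤ 12 subjects all 2ⁿ sign
patterns are enumerated (so p-values are exact and include the identity);
otherwise 1000 Monte-Carlo flips with the (1 + count)/(1 + n_perm)
estimator.  Permutation counts use a 1e-10 relative tolerance so the
identity permutation and its sign mirror always count despite
floating-point rounding (under enumeration the minimal attainable p is
2/2ⁿ, because every sign pattern and its negation give identical maximal
|mass|).  Paired condition contrasts pass difference series to the same
machinery.  The RM-ANOVA uses standard per-effect subject-interaction
error terms (verified against pingouin); sums of squares below a 1e-10
relative floor are treated as numerically zero.  Cross-measure
correlations z-score both variables, and points whose Cook's distance
from the y-on-x simple regression exceeds the mean are excluded for the
sensitivity re-estimate (verified against statsmodels).  Bonferroni
correction divides α by the number of tests (3 model parameters; 6
measure pairs).

## Behavior

RTs above the individual median + 2 SD (SD over all responses, strict
inequality) are excluded.  d′ and criterion treat identity A as the
signal and use the log-linear correction (+0.5 per count, +1 per
denominator), which keeps perfect performance finite and makes the
label-swap symmetry (d′ invariant, criterion sign-flipped) exact.  In the
jittered condition only targets preceded by a 1 s interval are analysed.
Misses are not modelled (the simulator always responds); accuracy is
percent correct of included responses.

## Problem sizes and reproducibility

The default `RunConfig` is desk-scale: 1 rhythmic + 2 jittered blocks of
12 trials, ~40–50 analysed chords per condition per subject, a 20 ms lag
grid, 20 ms response-offset grid, 6 SVD modes per family, and reduced PLV
grids.  These sizes were chosen so a full virtual subject analyses in
seconds while every estimator still operates in its intended regime; the
recovery tests use 3 + 6 blocks (the full design's block ratio), and
`RunConfig.paper_scale()` restores full-size settings (22 subjects,
60-trial blocks, 10/5 ms grids, full sensor counts).  All randomness
derives from a master seed through named, collision-free seed streams
(`stage_seed`), making complete runs bit-reproducible; group-level
permutation and sampling steps take their own derived seeds.

## Known limitations

* The forward model has no biophysics: recovery results validate the
  statistics, not source-level interpretation.  Source reconstruction is
  out of scope.
* Gain is injected directly as response scaling; the pipeline cannot
  distinguish "excitability gain" from any other mechanism that scales
  evoked SNR in the same window.
* The Gaussian-in-Δf tuning profile is one convention among several; σ
  estimates are only comparable within this convention.
* At very small trial counts (a handful of trials per band) distance
  matrices contain many missing cells and class fits may be skipped with
  a warning; group code treats these as missing.
* Single-staircase estimates of the converged level carry ~3 points of
  accuracy spread; replicate averaging is required for tighter estimates.
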