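# Methods

`shiftdecode` re-creates, as a tested pipeline on simulated data, an
occluder-paradigm fMRI analysis that measures how spatially precise the
contextual feedback signal to primary visual cortex (V1) is. A classifier
is trained to tell two natural scenes apart from V1 multivoxel patterns and
then tested on spatially shifted versions of the same scenes; the largest
shift at which decoding still transfers estimates the precision of the
information that higher visual areas feed back to V1.

## The generative model

### Scene patterns and the similarity kernel

Each scene × shift condition is represented by a zero-mean, unit-variance
voxel pattern. Spatial tuning is a single parameter, the kernel width
σ (degrees of visual angle): the expected correlation between patterns of
the same scene at shifts s₁ and s₂ is

    ρ(Δ) = exp(−Δ² / 2σ²),   Δ = |s₁ − s₂|.

Patterns for the three shift levels of a design are drawn *jointly*
Gaussian with covariance K[s₁,s₂] = ρ(|s₁−s₂|) (via the Cholesky factor of
the 3×3 kernel matrix). A simpler alternative — anchoring at shift 0 and
mixing a shared component with fresh noise — reproduces ρ only for pairs
involving the unshifted pattern and gives ρ(s₁)·ρ(s₂) otherwise; for
σ = 2.4° that would make the 3°↔7° pair (the only source of the 4° test)
essentially uncorrelated (0.007 instead of 0.25). The joint construction
makes every pair's correlation exactly ρ(Δ), which is the property the
cross-classification analysis actually probes. Patterns of different
scenes are independent.

### Voxel populations

The simulated slab holds four ground-truth populations (defaults, all
configurable via `VoxelLayout`): 150 *feedback* voxels (respond to the
occluder-mapping target checkerboard, amplitude 1.0, plus a weak mean image
response of 0.3 and the snr-scaled scene pattern), 150 *feedforward* voxels
(respond to all six image conditions, amplitude 1.0, pattern scaled by
snr × `feedforward_gain`), 150 *surround* voxels (respond to their
checkerboards at 1.0 and non-specifically to images at 0.5, no scene
pattern) and 150 pure-noise voxels. 150 voxels is the order of a small
single-subject fMRI ROI.

`feedforward_gain` (default 3) exists because directly stimulated cortex
decodes far better than the occluded region (near-ceiling versus ~67%
single-trial accuracy); one shared pattern amplitude cannot produce both
regimes.

### Timing

Defaults follow the block design: 12 s trials (30 flashes of
200 ms on / 200 ms off; the flicker only justifies the arithmetic — at
TR = 1 s a trial is simulated as a 12 s boxcar), six randomised 72 s
sequences of the six image conditions per run, one 72 s mapping sequence
(each checkerboard twice), 12 s fixation before every sequence and after
the last, four runs, two dummy volumes per run that are generated and later
discarded. This yields 600 task seconds per run; the published run length
(12 min 48 s) cannot be reconstructed exactly from the stated elements, and
no analysis quantity depends on it.

### Noise

Voxel noise is stationary AR(1) (lag-1 coefficient 0.3, SD 1 BOLD unit)
plus per-voxel slow drift (random linear + half-cosine, amplitude 0.5) and
a per-trial scalar amplitude jitter (SD 0.1) shared across voxels. These
are generic fMRI noise magnitudes, chosen once; pattern amplitude is
expressed relative to the noise SD (`snr`). Field maps, physiological
noise, motion and multi-echo effects are not modelled.

### Seeds

All randomness derives from one master seed through
`SeedSequence((master, stage, index, ...))` with fixed stage keys, so any
subject, run or analysis stage can be regenerated in isolation and whole
studies are bit-reproducible.

## The analysis

1. **Single-trial GLM** (per run): one boxcar regressor per trial convolved
   with a canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6,
   peak-normalised), confounds = intercept + linear trend + discrete-cosine
   high-pass set below 0.006 Hz; ordinary least squares per voxel. OLS
   rather than prewhitened GLS: betas feed a classifier, not parametric
   tests. Note that with AR(1) noise the *localiser* t statistics are
   inflated (~1.8× at φ = 0.3); the ROI threshold (default t > 3,
   configurable) is therefore a descriptive cut, not a calibrated α level.
2. **ROI selection** from a condition-level GLM across runs (shared
   condition regressors, run-wise confounds). Feedback ROI: t(target −
   near-surround) > threshold, excluding voxels responding to either
   surround checkerboard (minimises lateral spillover). Feedforward ROI:
   conjunction of all six image-vs-baseline contrasts, excluding
   checkerboard responders — the stand-in for the anatomical restriction to
   the contralateral stimulated hemisphere, which is out of scope here
   (no retinotopy is simulated).
3. **Decoding**: linear SVM (C = 1) on feature-wise z-scored betas
   (statistics from the training folds only), leave-one-run-out. Train on
   one shift, test on the same or another shift; for cross-shift pairs the
   two train/test directions are averaged, since one number per shift
   difference Δ is reported. Test modes: single-trial (ST) scores each
   held-out trial; average-block (AB) scores the per-condition mean of the
   held-out run's trial betas. Decision ties break toward scene 1.
4. **Inference**: two-level percentile bootstrap (1000 + 1000 samples) —
   fold accuracies resampled within subject, subject means resampled for
   the group mean and its middle-95% interval, reported as a pair of
   non-negative offsets below/above the mean. A condition counts as
   decodable only if the interval excludes 50% *and* the mean is above
   chance (the raw two-sided interval check is recorded separately).
   Condition differences use a 1000-sample label-shuffling permutation test
   on absolute group-mean differences, top-5% criterion, add-one p-values.
5. **QC**: subjects whose feedforward delta-0 single-trial accuracy is not
   above chance by a one-sided binomial test (α = 0.05 over the pooled test
   trials) are excluded before pooling — chance-level stimulated-cortex
   decoding means the data carry no usable signal.
6. **Pooling**: experiments sharing a shift triplet are collapsed; each
   (ROI, Δ, mode) condition pools every subject whose design tested that Δ
   (Δ = 0 from all 26 subjects; Δ ∈ {2,6,8} from 15; Δ ∈ {3,4,7} from 11).
   The recovered precision is max{Δ > 0 : decodable} for a given ROI and
   mode.

## The reference cohort and snr calibration

The reference configuration simulates 26 subjects split 8/7/6/5 over four
experiments (shift sets {0,2,8}, {0,2,8}, {0,3,7}, {0,3,7} degrees) with
σ = 2.4°. The pattern snr is the one calibrated quantity: a pilot grid
(snr ∈ 0.005…0.03, ~12 cohorts per value) located the value at which the
delta-0 feedback single-trial group accuracy falls in the prescribed
60–75% band. snr = 0.015 gives ~67–75% across pilot seeds (0.018 already
overshoots to 76–80%) and is frozen as the default. Per-voxel snr is small
because a 150-voxel pattern aggregates it ~12-fold.

At this calibration the feedback ROI decodes across 2°, 3° and 4° but not
6°, 7° or 8° — a recovered precision of 4° — in roughly one half to three
quarters of replicate cohorts (seed-stream dependent); the failure modes
are borderline 4° significance
(n = 11) and occasional false positives at 6–8° (ρ(6°) = 0.044 is small
but not zero, and the percentile bootstrap at n = 15 is mildly
anticonservative). The majority vote over 20 replicates is robustly 4°.

## What a green test does and does not establish

The simulator reproduces the *statistical skeleton* the analysis assumes:
block timing, HRF dynamics, AR(1) noise, a parametric similarity decay,
distinct voxel populations. It does not reproduce image content, retinal or
cortical geometry, retinotopy, eye movements, attention, motion artefacts
or between-subject anatomical variability. Green tests therefore establish
that the *pipeline* is correct and calibrated (null decoding at chance,
nominal error rates, faithful recovery of a known tuning width) — not that
the biological claim is true; conversely, accuracies on simulated cohorts
match published magnitudes only because the snr was calibrated to one
anchor value, and no other number was fitted.

## Numerical choices

- High-pass filtering is regression on a DCT basis (all components below
  0.006 Hz) — a deterministic projection, testable against FFT oracles;
  the voxel mean can be kept or removed by flag.
- Degenerate bootstrap inputs (identical fold accuracies, single fold)
  return the sample value exactly rather than resampling.
- Gaussian kernel matrices get a 1e−12 diagonal jitter before Cholesky.
- Constant features receive unit scale in z-scoring.
- Rank-deficient designs raise, naming the collinear columns via pivoted QR.
- Permutation p-values use the add-one convention (never exactly zero);
  the observed difference is compared with ≥ under a 1e−12 slack so that
  exact ties count.

## Known limitations

- The percentile bootstrap under-covers slightly for n ≲ 15 subjects; the
  one-sided significance rule absorbs the below-chance half of that error
  but above-chance false positives at null deltas remain somewhat more
  frequent than nominal. This is a property of the published procedure
  itself, reproduced deliberately.
- Localiser t thresholds are nominal, not FDR-controlled, and AR(1)
  inflation applies (see above).
- The feedforward ROI's checkerboard-responder exclusion is a proxy for
  anatomy; with real NIfTI input and real masks the exclusion flag can be
  disabled.
- Real-data support covers the post-preprocessing stages only (4-D NIfTI +
  BIDS-style events + masks); motion correction, slice timing and spatial
  normalisation must have happened upstream.
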