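# shiftdecode

Cross-shift multivoxel pattern analysis (MVPA) of contextual feedback
signals in human V1 — as a reusable, tested pipeline on simulated fMRI
data.

## The problem

Neurons in primary visual cortex (V1) have small receptive fields, yet V1
activity also reflects *feedback* from higher visual areas that process
larger regions of a scene. One way to measure how spatially precise that
fed-back information is: occlude one image quadrant (so the corresponding
V1 region receives no informative feedforward input), train a classifier
to discriminate two natural scenes from that region's activity patterns,
and test the classifier on versions of the same scenes shifted by
Δ ∈ {2,3,4,6,7,8} degrees of visual angle. The largest Δ at which decoding
still transfers bounds the precision of the feedback signal.

Because the underlying human data are not deposited, this package ships a
generative simulator whose voxel patterns have a controlled similarity
decay across shifts,

    ρ(Δ) = exp(−Δ²/2σ²),

so the whole analysis — single-trial GLM → ROI selection → linear-SVM
cross-classification → two-level bootstrap + permutation inference — can be
validated end-to-end against a known ground truth, and then applied
unchanged to real (preprocessed) NIfTI data.

Audience: neuroimaging methodologists who want a calibrated testbed for
generalisation ("cross-classification") decoding analyses, and anyone who
needs the occluder-paradigm pipeline as a library.

## Worked example

Simulate the reference cohort (26 subjects split 8/7/6/5 across four
experiments; shift sets {0,2,8} and {0,3,7} degrees; Gaussian tuning
σ = 2.4°; pattern snr calibrated so unshifted feedback decoding lands at
~60–75%) and run the full pipeline:

```python
import shiftdecode as sd

cfg = sd.reference_config(seed=3)
res = sd.run_full_study(cfg)
fb = res.group_df.query("roi == 'feedback' and mode == 'ST'")
print(fb[["delta_deg", "group_mean_pct", "ci_lower_offset",
          "ci_upper_offset", "significant_vs_chance"]].to_string(index=False))
print("recovered precision:", res.precision["feedback"]["ST"], "deg")
```

prints (seed 3):

```
 delta_deg  group_mean_pct  ci_lower_offset  ci_upper_offset  significant_vs_chance
       0.0       72.534970         0.042848         0.044932                   True
       2.0       66.243811         0.045225         0.047964                   True
       3.0       61.420956         0.048929         0.061751                   True
       4.0       57.320181         0.038691         0.033663                   True
       6.0       50.351271         0.025360         0.027737                  False
       7.0       49.355554         0.038770         0.037909                  False
       8.0       51.414235         0.022173         0.024822                  False
recovered precision: 4.0 deg
```

Reading: single-trial accuracy (percent, with middle-95% bootstrap CI
offsets below/above the mean) decays with the train/test shift difference;
the CI excludes chance (50%) up to 4°, but not at 6–8°, so the fed-back
scene information generalises to about 4 degrees — the recovered tuning
width. Accuracies are stored as fractions and reported as percent;
`mode="AB"` rows hold the average-block variant, `roi="feedforward"` the
stimulated-region control (near-ceiling at Δ=0).

The same stages are available as a CLI, chained through files:

```bash
shiftdecode run-all --seed 3 --out-dir out/          # everything at once
shiftdecode simulate --seed 3 --out-dir out/         # or stage by stage:
shiftdecode glm --out-dir out/
shiftdecode roi --out-dir out/
shiftdecode decode --out-dir out/
shiftdecode infer --out-dir out/
shiftdecode report --out-dir out/                    # table + CI-bar figure
```

`--config cfg.yaml` overrides any default (designs, tuning, noise, voxel
layout, thresholds, bootstrap sizes); `shiftdecode simulate` also writes
BIDS-style exports (4-D NIfTI per run, events TSV, mask NIfTIs) via
`shiftdecode.io`, and real preprocessed data in that layout can enter the
pipeline at the GLM stage.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly simulated data: the grand-mean decoding accuracy
of a 100-subject zero-signal cohort (null calibration of the full
GLM + SVM stack), the empirical type-I error of the 1000-shuffle
permutation difference test over exchangeable-null replicates, and the
majority-vote recovered feedback precision over 20 replicate reference
cohorts. Runtime is a few minutes on one CPU; all randomness derives from
`--seed`.

See `docs/methods.md` for the generative model, calibration procedure,
numerical choices and limitations.
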