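# fearvox

Analysis toolkit for Pavlovian fear-conditioning fMRI with concurrent
pupillometry. It targets the classic differential-conditioning question —
does a region respond more to a threat-predicting stimulus (CS+) than to
a safe one (CS−)? — in a design where four stimuli (CS+/CS− × face/house)
recur over 13 trials each, shocks land only on designated *filler*
trials, and analysis uses the 7 shock-free *target* trials per condition.

The package covers the full chain:

- **design** — trial-schedule generation (52 trials, 28 targets, 24
  fillers, 46% CS+ reinforcement, volume-locked onsets, 8-trial
  habituation baseline) and first-level design matrices: double-gamma
  HRF convolution, temporal derivatives, motion confounds, named
  contrasts.
- **glm** — Gaussian smoothing, voxel-wise OLS, contrasts of parameter
  estimates (copes), percent-signal-change scaling.
- **inference** — group one-sample sign-flip permutation test with
  threshold-free cluster enhancement and max-statistic FWER control
  (exact enumeration for small n), plus a Freedman–Lane covariate mode.
- **roi_stats** — probabilistic-mask binarization, significant-voxel
  accounting with local maxima in world coordinates, susceptibility
  dropout (<50% of mean EPI signal), ROI condition means with 2×2
  repeated-measures ANOVA and paired t.
- **pupil** — the pupillometry pipeline: blink-gap cleaning (100 ms
  padding around ≥10-sample gaps, linear interpolation), zero-phase
  3rd-order Butterworth low-pass at 4 Hz, peak-minus-baseline responses
  (0–4 s window, 500 ms baseline), missing-trial replacement by
  across-trial linear trend, ≥1/3-missing subject exclusion,
  within-subject z-scoring, and the trial (13) × stimulus (CS+/CS−)
  repeated-measures ANOVA.
- **synthdata** — a multi-subject generator with known ground truth:
  condition-specific BOLD effects in percent signal change, drift,
  AR(1)+white noise, motion coupling, a planted dropout region, and
  event-locked pupil dilations with blinks.

The statistics in brief: first-level `y = Xβ + ε` per voxel with
`cope = c'β̂`; group inference builds the null of
`max over mask of TFCE(t)` by sign-flipping subject maps, with
`TFCE(v) = Σ_h e_h(v)^E · h^H · dh` (E = 0.5, H = 2, 26-connectivity)
and `p_corr = (1 + #{max_perm ≥ obs}) / (n_perm + 1)`. The 2×2
within-subject ANOVA reduces to squared paired t statistics;
the trial × stimulus ANOVA uses the univariate decomposition with
subject-interaction error terms, df (1, n−1) and (12, 12(n−1)).
See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Simulate a small group, fit first-level models, and run the group
permutation test on the learned-threat contrast:

```python
import numpy as np
from fearvox import design, glm, inference, roi_stats, synthdata

# 1. trial schedule
sched = design.build_trial_sequence(counterbalance_seed=7)
print(f"{len(sched)} trials, "
      f"{sum(t.role == 'target' for t in sched.trials)} targets, "
      f"{sum(t.reinforced for t in sched.trials)} reinforced")

# 2. synthetic group and first-level GLMs
hrf = design.hrf_double_gamma(0.1)
subjects, sched = synthdata.simulate_group(10, seed=7, schedule=sched)
copes = []
for bold, motion, truth in subjects:
    dm = design.build_design_matrix(sched, motion, hrf=hrf)
    fit = glm.fit_glm(bold, dm)
    cope = glm.compute_contrast(fit, "csp_vs_csm")
    psc = glm.percent_signal_change(cope, bold, dm, sched, hrf)
    copes.append(psc.values)

# 3. group sign-flip permutation test with TFCE
mask = subjects[0][0].mask
sample = inference.GroupSample.from_maps(copes, mask)
res = inference.permutation_test(sample, n_perm=500, seed=7)
print(f"significant voxels (FWER p < 0.05): {int(res.significant.sum())}")

# 4. compare with the planted CS+ regions
truth = subjects[0][2]
planted = truth.active_regions["csp_face"] | truth.active_regions["csp_house"]
rep = roi_stats.roi_report(res.significant, res.tmap, planted, truth.affine)
print(f"inside planted CS+ regions: {rep.n_significant}/{rep.n_mask_voxels} "
      f"({rep.percent:.1f}%), peak t = {rep.local_maxima[0][3]:.2f}")
```

Output:

```
52 trials, 28 targets, 12 reinforced
significant voxels (FWER p < 0.05): 4
inside planted CS+ regions: 4/54 (7.4%), peak t = 8.23
```

The schedule reproduces the design's trial accounting (52 trials; 12
reinforced = 6 per CS+ condition, all fillers). At this deliberately
small scale (n = 10 subjects, 500 permutations, 1% planted CS+ effect
against 1% noise) the FWER-corrected map detects 4 voxels — every one of
them inside the planted CS+ cubes, none elsewhere: the correction is
strict, so detections are sparse but clean. The peak t of 8.23 sits at a
planted-region voxel.

A `fearvox` CLI wraps the same functionality
(`fearvox simulate | grouplevel | roi | pupil | schedule`); try
`fearvox schedule --seed 7`.

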