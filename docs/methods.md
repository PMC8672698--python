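# Methods

`fearvox` implements the analysis chain for a Pavlovian fear-conditioning
fMRI experiment with concurrent pupillometry: the trial-schedule
generator, first-level GLM, group permutation inference with
threshold-free cluster enhancement (TFCE), probabilistic-ROI statistics,
the pupil-response pipeline, and a synthetic-data generator with known
ground truth. This note records the model, its assumptions, and the
design choices made where the procedure left them open.

## Experimental design

The conditioning phase presents four conditioned stimuli — CS+ face,
CS− face, CS+ house, CS− house — for 4 s each with a 20 s interstimulus
interval (a 6 s / 22 s preset covers the older acquisition variant). Each
condition occurs on 13 trials: 7 *targets*, used for estimation, and 6
*fillers*. Every CS+ filler co-terminates with the shock (US), yielding
6/13 ≈ 46% reinforcement per CS+ while keeping target trials shock-free.
The US is modelled as two pulses, the first 300 ms before stimulus
offset, the second at offset.

Targets come in repeating blocks of four (one per condition, in a
seed-determined order that is fixed across blocks — a stand-in for the
across-participant counterbalancing, whose exact scheme is not public).
The first two blocks (8 trials) run uninterrupted and unreinforced as a
habituation baseline. After them, one or two fillers are inserted into
the gaps between successive targets until all 24 are placed, the extra
slots drawn from the seed. The generator then verifies that no target
onset falls within 8 s of a shock, so shock-related activity cannot
contaminate target-locked estimates; with the default 24 s
stimulus-onset asynchrony this margin always holds. All onsets are
locked to volume acquisitions (TR 2 s).

## First-level model

Each event stream is represented as a boxcar at 0.1 s resolution,
convolved with a double-gamma haemodynamic response function, and
sampled at volume onsets. The HRF is the difference of two gamma
densities, the undershoot scaled by 1/6, peak-normalised. Each gamma is
parameterised by its **mean** (peak delay 6 s, undershoot delay 16 s)
and **variance** (dispersion 3 s² for both), putting the positive lobe's
mode near 5.5 s. The mean/variance parameterisation was chosen over
shape/scale conventions because it keeps the peak in the canonical
5–6 s range at these dispersion values; the kernel is exactly 0 at t = 0
and negligible beyond 32 s.

Regressors of interest are the four CS target regressors (7 events
each). Regressors of no interest: one filler regressor (all 24 filler
events), a US regressor, the temporal derivative (backward difference)
of each task regressor, the six motion parameters with their first
differences, and a constant. Contrasts use unit-sum-of-positive weights
(±0.5), so `csp_vs_csm` and `face_vs_house` read directly as
condition-mean differences.

Estimation is ordinary least squares per voxel; degrees of freedom are
n_volumes − rank(X). No prewhitening is applied: group inference is
permutation-based and does not require first-level whiteness, and the
synthetic AR(1) noise is mild (coefficient 0.3). Smoothing (Gaussian,
FWHM 2/5/8 mm, per-axis sigma for anisotropic voxels) precedes the GLM
and is applied without mask-edge renormalisation, as in standard
volumetric pipelines.

Percent signal change scales a cope by
`100 × peak(unit event response) / voxel temporal mean`, where the unit
response is one stimulus-length boxcar convolved with the HRF. This
makes a planted 1% amplitude in the generator read out as PSC ≈ 1.0 and
renders the map invariant to global intensity rescaling. Voxels with
non-positive temporal mean are dropped from the mask with a warning.

## Group inference

The one-sample test sign-flips subject cope maps: under a symmetric null
each subject's map can change sign without changing the joint law. For
each flip pattern the t map is recomputed, TFCE-enhanced, and its
maximum over the mask recorded; corrected p-values are
`(1 + #{max_perm ≥ tfce_obs}) / (n_perm + 1)`, which includes the
identity permutation and guarantees validity. When `2^n ≤ n_perm` all
sign patterns are enumerated and p-values are exact, deterministic and
seed-free. Two-sided questions are answered by two one-sided runs
(positive and negated maps), each at α = 0.05, matching how the two
contrast directions are reported separately.

TFCE uses the method's standard settings — E = 0.5, H = 2,
26-connectivity, 100 thresholds with dh = max/100 — enhancing the
positive part only. Suprathreshold membership is `stat ≥ h`. The kernel
sweeps thresholds from the top down over height-sorted voxels with an
explicit-stack flood fill (numba-compiled, since permutation nulls need
thousands of transforms); an independent per-threshold component-labeling
oracle (scipy.ndimage) verifies it in the tests. Zero-variance voxels
get t = 0 by convention. No variance smoothing is applied.

The covariate mode fits `cope ~ intercept + covariate` (covariate
demeaned; e.g. trait anxiety or differential pupil response) and tests
the slope t with Freedman–Lane permutation: intercept-model residuals
are permuted, which for this design is equivalent to permuting covariate
entries, under the same max-TFCE correction. A constant covariate is an
error.

## ROI statistics

Probabilistic masks accept 0–1 or 0–100 encodings (values above 1 imply
percent). Binarization is strict (`p > threshold`) at 0.01 / 0.25 /
0.50. Significant-voxel reports count `sig ∩ roi` voxels and list local
maxima: voxels whose statistic is ≥ all face-connected neighbours inside
the region, flat plateaus reduced to the lowest flat index, converted to
world mm via the affine and sorted by descending statistic.

Susceptibility dropout follows the <50% rule: a ROI voxel is flagged
when its mean EPI intensity falls below half the subject's whole-brain
mean EPI signal (the reference the original criterion leaves implicit);
the report is scale-invariant by construction.

Mean-signal-change analysis averages PSC maps over the ROI per subject
and condition. The 2×2 within-subject ANOVA (picture type × learned
threat) exploits the two-level structure: each effect F equals the
squared paired t on its difference scores, df = (1, n−1), partial
η² = F/(F + df₂). The ANOVA is run per hemisphere mask, and is invariant
to per-subject offsets. A paired t compares the face−house and CS+−CS−
differences directly.

## Pupil pipeline

Order is fixed and asserted by test: clean → filter → extract →
replace/exclude → z-score. Filtering before cleaning would smear blink
artifacts into valid samples.

1. **Cleaning.** Runs of ≥10 invalid samples are extended by 100 ms on
   each side (25 samples at 250 Hz, 50 at 500 Hz) and marked invalid;
   all invalid samples are then linearly interpolated between the
   nearest valid neighbours (edge runs: constant extension). "Linear
   trend at point" is implemented as within-trace linear interpolation.
2. **Filtering.** Third-order Butterworth low-pass at 4 Hz, zero-phase
   (forward–backward), chosen to avoid shifting response-peak latencies.
3. **Extraction.** Response = max diameter in (onset, onset + 4 s] minus
   the mean over the 500 ms before onset. Windows outside the trace mark
   the trial missing.
4. **Replacement and exclusion.** A trial is missing when more than 50%
   of its baseline or response samples were invalid *before* cleaning.
   Missing responses are replaced by evaluating an OLS line fitted over
   that condition's non-missing (trial index, response) pairs — the
   across-trial linear trend — per original four-level condition, before
   face/house averaging; conditions with fewer than two usable trials
   fall back to the condition mean with a warning. Subjects with ≥1/3
   missing trials in a phase are excluded; the denominator is the whole
   phase (52 trials), the per-condition alternative being unstated in
   the source procedure.
5. **Averaging and z-scoring.** Face and house variants of the same
   threat value are averaged per trial index (13 CS+ and 13 CS− trials),
   then responses are z-transformed across all 26 trials within subject
   and phase. Averaging precedes z-scoring because the transform is
   defined across all trials and the analysis operates on CS+/CS−
   averages. Baselines use post-filter samples.

The trial (13) × stimulus (2) repeated-measures ANOVA uses the
textbook univariate decomposition with subject-interaction error terms,
sphericity-uncorrected dfs — stimulus (1, n−1), interaction
(12, 12(n−1)) — and is implemented as vectorised sums of squares so the
label-shuffled null of the power experiment is cheap;
statsmodels' AnovaRM reproduces it to machine precision in the tests.

## Synthetic data

The generator is the test bed for every stage. BOLD runs are
`baseline 1000 × (1 + Σ_c amp_c/100 · regressor_c / peak)` on a
24×24×12 grid of nominal 2 mm voxels, plus polynomial drift (order 2,
sd 0.5% of baseline per order), AR(1)+white noise (coefficient 0.3,
white sd 1% of baseline), and a motion-coupled nuisance driven by
smooth random-walk motion parameters. Effects live on 27-voxel cubes
(one per condition, default amplitudes 1% for CS+ and 0.5% for CS−, a
plausible conditioning-effect magnitude); filler trials evoke the mean
amplitude through the shared filler regressor, keeping the signal inside
the model span so noiseless round trips are exact. A cube near the
volume's edge is scaled to 0.3× baseline to mimic susceptibility
dropout. Group simulation draws subject amplitudes Normal(template,
between-subject sd 0.2%) with independent noise seeds derived from the
master seed.

Pupil traces are slow baseline wander plus gamma-shaped event-locked
dilations (peak ≈ 1.3 s) with white noise (sd 0.02 a.u.) and
Poisson-scheduled blink gaps (6/min, 100–400 ms). Default amplitudes
follow the acquisition pattern: CS+ grows linearly 0.15 → 0.45 a.u.
across its 13 trials while CS− stays at 0.15, reproducing the
trial-by-trial differential learning curve.

What the generator does **not** emulate: EPI physics (distortion
fields), physiological noise beyond AR(1)+drift, spatial autocorrelation
of the noise field, pupil foreshortening or gaze dependence. Passing
tests therefore demonstrate correctness of the estimators and validity
of the permutation inference under the assumed noise structure, not
performance on real scanner data.

## Validation experiments and problem sizes

Three standing simulations (module `experiments`) validate inference
end to end; the acceptance script and test suite run them at these
sizes, chosen to give stable estimates at desk scale:

- **Null calibration**: 200 datasets of n = 12 standard-normal cope
  maps on an 8×8×6 mask, 500 permutations each; the family-wise error
  rate at α = 0.05 must fall in the binomial band [0.02, 0.09].
- **Planted-effect recovery**: 20 datasets of n = 16 with a 27-voxel
  cube at between-subject d = 2.0 on a 16×16×10 mask, 1000
  permutations; sensitivity inside the cube is expected ≥90%. False
  positives outside a 1-voxel dilation of the cube are counted and
  expected near zero; note that a correctly calibrated 5% FWER test
  still produces some dataset-level false positive in roughly one of 20
  datasets, so occasional single-voxel detections outside the cube
  reflect the nominal error rate, not miscalibration (the null
  calibration above checks calibration directly).
- **Pupil interaction power**: 100 simulated groups of 8 subjects run
  through the full trace pipeline; the trial × stimulus interaction F
  must exceed the 95th percentile of a stimulus-shuffled null (labels
  swapped within subject and trial) in ≥95% of groups.

## Numerical choices and degenerate inputs

- Permutation t maps are computed chunk-wise with the direct mean/sd
  formulas; the sum-of-squares shortcut loses precision on
  near-degenerate flip patterns and is not used.
- TFCE ladder is relative to each map's maximum; an all-zero (or
  all-negative) map returns zeros.
- Zero-variance voxels: t = 0. Zero-variance paired differences:
  t = 0, p = 1 when all-zero, ±∞ with p → 0 otherwise. Degenerate
  ANOVA error terms: F = 0 when the effect sum of squares is also null,
  ∞ otherwise.
- Events extending past the scan end are truncated with a warning; an
  event stream with no events yields an all-zero column.
- Probability masks whose values exceed 1 are decoded as percentages.

## Known limitations

- No prewhitening or slice-timing correction (the latter intentionally
  out of scope); first-level variance estimates are therefore mildly
  biased under autocorrelated noise, which the permutation group test
  tolerates by construction.
- The counterbalancing scheme is a seeded permutation, not the
  original lab's (unpublished) assignment table.
- Atlas lookups for labeling cluster peaks are out of scope; reports
  carry coordinates only.
- The exhaustive-enumeration path is quadratic in memory over
  (patterns × voxels) and intended for small n.
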