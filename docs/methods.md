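# Methods

This note documents the models, parameter choices and numerical
conventions behind `pupilcc`, and what the synthetic-data tests do and do
not establish about real recordings.

## Signal model and preprocessing

The pipeline treats the pupil record as a binocular 60 Hz diameter stream
with per-eye validity flags. The two eyes are combined by averaging; a
sample is missing whenever *either* eye is invalid. The alternative —
falling back to the single valid eye — would treat monocular samples as
trustworthy, but lid closure and tracking loss usually distort the
surviving eye too, so the conservative binocular rule is used and
monocular samples are interpolated instead.

Missing runs are padded by 3 samples (50 ms) on each side before
interpolation, because samples adjacent to a blink are contaminated by
the closing/opening lid. Interpolation is linear **against real
timestamps**, not sample indices, so jittered grids are handled
correctly. Runs touching a trace boundary lack an anchor on one side and
are filled by holding the nearest valid value; this keeps epochs
rectangular, and such samples still count toward the exclusion fractions,
so trials dominated by boundary fills are dropped anyway. The exclusion
fraction counts *interpolated* (post-padding) samples, not raw invalid
samples.

## Epochs, baseline, windows

Epochs span −500 ms to +3000 ms around stimulus onset: the span must
contain the 500-ms pre-stimulus baseline, all three summary windows, and
the latest cluster offsets the waveform statistics can reasonably report;
overlap with the following trial is accepted because analyses only read
defined windows. Onsets are mapped to the first sample at or after the
onset time and a fixed vector of sample offsets defines every epoch, so
all epochs of a recording share one relative-time grid; on a uniform grid
this is identical to direct timestamp filtering of the half-open
interval.

All interval membership is start-inclusive, end-exclusive on the
nearest-sample grid: a window `[a, b)` in ms selects offsets
`round(a·rate/1000) ≤ k < round(b·rate/1000)`. Doing the arithmetic in
index space avoids float-boundary artifacts (e.g. 66·(1000/60) being
1100.0000000000002).

Dilation is diameter minus the mean diameter over `[-500, 0)` ms. A trial
is excluded when **more than** 70% of the samples in the baseline and/or
the task's summary window were interpolated — fractions exactly at 0.70
are kept. A stricter 0.50 threshold is available through the same
argument. Summary windows are 500 ms long and task specific (2-Back
1100–1600 ms, Stroop 1000–1500 ms, Number Switch 1300–1800 ms). A
reproduction aid, `waveform.select_window`, re-derives such windows from
data: among all width-length windows containing the global peak of the
grand-average curve it maximises the mean |t| of the condition contrast
("maximally sensitive"), falling back to the mean of the curve and then
to the earliest start on ties.

## Waveform statistics

Condition waveforms are subject-level means over included, correct trials
(a configurable minimum trial count per subject, default 1). The contrast
is a two-tailed paired t-test at every sample (df = n−1). Zero-variance
differences are degenerate; they are reported as t = ±inf, p = 0 when the
mean difference is non-zero (and t = 0, p = 1 otherwise), a documented
convention rather than a statistical claim. Multiplicity over time is
controlled by contiguity: only runs of at least 6 consecutive samples
(100 ms at 60 Hz) with p < 0.001 are reported, with cluster bounds given
as the times of the first and last member samples. The null
false-positive rate of this rule is checked empirically by simulation
(below), not derived analytically.

## Behavioral scoring

* **2-Back**: within each block, trial *t* is a match iff its letter
  equals the letter at *t−2*; the first two trials of a block have no
  comparison stimulus and are excluded from error and RT denominators.
  A trial is "correctly encoded" when the trial two positions later was
  answered correctly. Error percentages use scorable trials as the
  denominator.
* **Stroop**: congruency is word = ink; the interference effect is the
  incongruent-minus-congruent difference in mean correct RT and in error
  percentage.
* **Number Switch**: only the two mixed blocks are scored; a trial is a
  switch trial when its cue colour differs from the previous trial's, and
  each mixed block's first trial is unlabeled (no predecessor). The
  correct-response cost is computed as a *rate* difference (switch minus
  non-switch), not a count difference.
* Filters: RTs below 300 ms are flagged in the 2-Back and Number Switch
  tasks (the Stroop task is exempt; its 3000-ms window makes fast guesses
  rare and the floor is not part of its preparation). Correct-trial RTs
  deviating more than 3 SD from their subject × task × condition cell
  mean are flagged in the Stroop and Number Switch tasks, in a single
  pass (no re-estimation after removal). The within-cell reference was
  chosen because pooled trimming would confound subject speed differences
  with trial exclusion. Between-subject screening flags values more than
  3 SD from the group mean, per measure only, so a subject extreme on one
  index still contributes elsewhere. Omissions (no response within the
  window: 1500 ms in 2-Back, 3000 ms otherwise) are scored as errors.
  Error counts are square-root transformed before correlational analyses
  to reduce right skew.

## Between-subject statistics

Correlation matrices use pairwise deletion, matching the per-measure
subject screening. Forward stepwise regression standardises y and the
candidates, enters at each step the candidate with the smallest F-change
p while it is below the entry criterion (default α = 0.05; 0.10 is
accepted via configuration since the reporting convention only bounds
non-improvement at p > 0.10), and reports standardized β, t with its
residual df, p, and each predictor's squared zero-order correlation with
y. When candidate predictors correlate at |r| ≥ 0.90 the fit is refused
with a multicollinearity diagnostic naming the offending pair, because
unique contributions are not interpretable in that regime (the analysis
then falls back to inspecting correlations). Two-level repeated-measures
contrasts are computed from the paired t-test: F = t², df = (1, n−1),
ηp² = F·df1/(F·df1 + df2).

## The synthetic study generator

The generator's role is to produce data with exactly the statistical
structure the analysis assumes, so every stage can be scored against
ground truth. A subject's continuous signal is

    baseline_s + Σ_trials amp(condition, correctness, s) · prf(t − onset) + AR(1)

with the unit-peak pupil response kernel
`prf(t) = (t/t_max)^n · exp(n(1 − t/t_max))`, shape n = 10.1. Kernel
peaks are placed inside each task's summary window (t_max = 1350 / 1250 /
1550 ms for 2-Back / Stroop / Number Switch) so that default simulations
exercise the default windows. Amplitudes are specified on the scale of
the measured window mean: each trial's kernel is scaled by the
reciprocal of the kernel's mean over the task's summary window, so a
configured amplitude is also the expected window-mean dilation.

Per-trial amplitude = condition base + 0.08 mm error increment (errors
dilate more) + 0.040·θ_s + 0.069·η_s (± half the per-subject contrast
effect δ_s, SD 0.02 mm, for Stroop/Switch). θ_s ~ N(0,1) is the latent
effort of subject *s*; η_s ~ N(0,1) is effort-independent pupil
reactivity. Condition bases default to the published group descriptives
(2-Back 0.098, congruent 0.110, incongruent 0.152, non-switch 0.131,
switch 0.171 mm). Behavioral errors follow
p_err = logistic(intercept_c − 1.1·θ_s) with intercepts solved
numerically so the error rate *marginalised over θ* matches the published
condition means (e.g. −2.17 for the 2-Back's 14.3%); RTs are lognormal
(trial σ = 0.25, subject σ = 0.10 on the log scale) with means matching
the published condition RTs; draws above the response window become
omissions.

The effort coupling is the deliberate source of the
individual-differences structure: with these defaults the *generating*
correlation between a subject's 2-Back amplitude and expected error count
is ≈ −0.48 (≈ 0.040/√(0.040² + 0.069²) times the θ–error correlation of
≈ −0.96), i.e. the −0.5 regime of the published r = −0.51 anchor. The
pipeline recovers ≈ −0.43 on 200-subject cohorts; the shortfall is
ordinary attenuation by AR(1) measurement noise in the window means and
by binomial noise in the error counts.

Noise is AR(1) with φ = 0.9 and stationary SD 0.10 mm — temporally smooth
like real pupil noise and strong enough that single-trial dilation is
unreliable while condition means over ~30 retained trials are stable.
Artifacts are two Poisson processes with geometric run lengths: blinks
(0.25/s, mean 8 samples) and tracking dropouts (0.12/s, mean 90 samples),
jointly tuned once so that interpolation-based exclusion keeps ≈ 73–75%
of trials, the regime the exclusion rule is designed for. Both eyes share
the artifact mask and carry independent 0.02 mm white noise.

Task designs are constraint-exact and verified by rescans: the 2-Back
sequence contains exactly 34 matches in 90 trials (17 per block by
default; the global 34-of-90 figure does not pin down the per-block
split, so an even split is used and is configurable), with non-match
trials drawn from the alphabet excluding the letter two back so no
accidental matches arise; Stroop blocks contain exactly 18 congruent and
18 incongruent trials from a 3-word × 3-colour set; the Number Switch
task has two single-colour blocks (order counterbalanced by subject
parity) and two mixed blocks with per-trial random colours. Trial onsets
follow stimulus hold (until response or timeout) plus a 2000-ms ITI.

All randomness flows from one root seed through per-subject,
per-task `SeedSequence` spawns, so studies are bit-reproducible and
subjects are independent streams.

### What the generator does not emulate

Gaze position and pupil foreshortening, luminance responses (the
experimental design holds luminance constant), saccade- or
accommodation-driven transients, non-stationary drift (fatigue), response-
or feedback-locked dynamics, sequential effects (post-error slowing,
congruency sequence effects), and any dependence of the pupil response
*latency* on condition or effort — only amplitudes vary. Passing
parameter-recovery tests therefore shows the pipeline is correct and
well-calibrated under its own assumptions, not that those assumptions
hold for a given real dataset.

## Monte-Carlo test sizes

The recovery checks in the test suite use sizes chosen to balance
statistical resolution against runtime: 200 simulated null studies of 35
subjects (Stroop only) for the false-positive rate of the cluster rule;
20 simulated effect studies of 35 subjects for detection/localisation;
one 200-subject 2-Back cohort for the dilation–error correlation; 60
subjects for amplitude calibration. The end-to-end default run analyzes
35 subjects across all three tasks.

## Known limitations

* The eye-combination rule and the boundary-hold interpolation are
  documented choices where hardware pipelines differ; both are isolated
  in single functions.
* Stepwise selection inherits the usual caveats (post-selection inference
  is optimistic); the package reports rejected candidates' F-change
  p-values and the model n so users can judge.
* The zero-variance p := 0 convention makes degenerate contrasts
  maximally significant by fiat; degenerate cases are flagged in the
  output.
* Cluster bounds are member-sample times on the 60 Hz grid; reported
  onsets/offsets are therefore quantised to ~16.7 ms.
* `select_window` reproduces the window-selection heuristic but the
  shipped task windows remain the defaults; re-derived windows can differ
  by a few samples on noisy data.
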