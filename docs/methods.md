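# Methods

## The paradigm and the quantities computed

Each trial of a paired-image free-viewing session begins with the subject
holding gaze inside a 3.0° × 3.0° central fixation window; a face image and
an anogenital-region (AGR) image of the same stimulus monkey then appear in
two disjoint display windows, one on each side of the screen, for 3 s.
Gaze position (degrees of visual angle, origin at screen centre) and pupil
size (arbitrary tracker units) are sampled at 1000 Hz.

The pipeline reduces each trial to:

- in-window fixation counts and dwell times per AOI (face / AGR);
- `pAGR = n_AGR / (n_AGR + n_face)`, the proportion of in-window fixations on
  the AGR image (missing when a trial has no in-window fixation);
- the *first gaze*: the AOI of the first post-onset fixation whose centroid
  lands in either image window, skipping off-image landings;
- ROI tallies (forehead, eyes, nose, mouth, other) for face fixations;
- per-fixation mean pupil, z-scored against the session baseline.

Off-image fixations enter no headline metric; they are tallied separately
(`n_fix_off`) for quality control.

## Fixation detection (I-DT)

Detection is dispersion-threshold identification: grow a sample window while
`(max x − min x) + (max y − min y) ≤ dispersion` and emit a fixation once the
window spans at least the minimum duration; the scan is greedy left-to-right
(the window start advances one sample at a time until a minimum-duration
window fits under the threshold, then the end extends as far as the threshold
allows). Defaults: dispersion 1.0°, minimum duration 60 ms, blink padding
50 ms, merge gap 20 ms. A sample stamped `t` covers `[t, t+1)` ms, so a
window `t_first..t_last` has duration `t_last − t_first + 1`.

Blink intervals — maximal runs of zero-pupil or invalid samples, padded
±50 ms and unioned — are masked before the scan, and a blink always
terminates the current window. Consecutive fixations separated by less than
the merge gap are merged when their union still fits the dispersion cap.
The greedy scan is verified exactly against a naive maximal-window
enumeration oracle in the test suite.

Two properties of I-DT worth knowing. First, detected fixations absorb the
slow tail of the preceding saccade sweep, so onsets/offsets shift by up to
`dispersion / sweep-speed` milliseconds; the generator's minimum landing
separation (below) bounds this at the merge gap (20 ms). Second, under
per-sample i.i.d. position noise the greedy window often locks in with
near-zero dispersion margin and then fragments a fixation in two; this is a
known fragility of the classic algorithm, not of this implementation. The
noise-robustness test therefore adds Gaussian noise at 1/100 of the
dispersion threshold, where fragmentation is mild; at noise levels
approaching the threshold over ~6, I-DT measurably over-segments
(≈ +20% fixation count at SD = 0.05° in our measurements).

## The synthetic-gaze generator

The generator emits 1000 Hz sample logs with the behavioural structure the
analysis assumes, plus a ground-truth record (true fixation intervals,
targets, first-gaze labels) for parameter recovery. Per trial: a 500 ms
central-fixation baseline, an initial 40 ms saccade away from centre, then
alternating fixations and 40 ms linear sweeps until the 3 s display ends
(the final fixation is extended to the display end when no further full
fixation fits).

Structural choices:

- **Targets.** The first fixation lands on the AGR window with probability
  `q_first` (optionally shifted by a side bias); each later fixation is
  i.i.d. Bernoulli(`theta_pagr`) between AGR and face, so the generative
  mean of pAGR is θ exactly and recovery tests are sharp. An optional
  stay-probability turns the sequence into a sticky Markov chain with the
  same stationary mean. Both parameters are dicts keyed
  `"TREATMENT:image_sex"` (optionally refined by age class × familiarity).
  Defaults: θ female 0.68 / 0.70 / 0.71 and male 0.69 / 0.69 / 0.70 across
  saline / oxytocin / testosterone; q female 0.78 (0.84 under testosterone),
  male 0.81 — the condition means such experiments report.
- **Durations.** Lognormal, calibrated so the distribution has exactly a
  requested mean and median: μ = ln(median), σ = √(2 ln(mean/median)).
  Defaults calibrate to mean 246.65 ms / median 213.00 ms, the canonical
  free-viewing fixation-length scale; draws under an 80 ms floor are redrawn
  so every true fixation is detectable at the 60 ms minimum duration.
- **Landing points.** Face landings follow a mixture over ROI polygons
  (defaults: forehead 0.345, eyes 0.35, nose 0.08, mouth 0.07, other 0.155 —
  the forehead/eye dominance typical of macaque face viewing); AGR landings
  are uniform in the window (0.3° edge inset). Consecutive landings are
  redrawn until at least 2.0° apart: closer pairs would let a fixation
  window bridge the sweep, making truth ill-defined for a dispersion
  detector; the constraint perturbs the realised ROI mixture by under a
  percentage point (the ROI-recovery test allows 4 multinomial SE + 0.01).
- **Off-image gaze.** Non-initial fixations land off-image with a per-sex
  probability (female 0.12, male 0.55), calibrated so in-window counts per
  trial match the ~10 (female) and ~5.5 (male) means such sessions show when
  the overall fixation stream runs at ~11 per 3 s. The per-trial propensity
  is Beta-distributed around the sex mean (concentration 12), modelling
  trial-level engagement: this is what makes in-window count and dwell
  strongly positively correlated across trials, as observed empirically —
  with on-image gaze saturated, the two would be weakly *negatively*
  coupled, since more fixations mean more saccade overhead in a fixed 3 s.
- **Positions.** Within a fixation the emitted position is exactly the
  landing point (the spec'd signal is drift-free; tracker noise is a
  test-time addition, see the I-DT note above). Sweeps interpolate linearly.
- **Pupil.** `pupil = session_base + offset_z · σ_noise + AR(1) noise`, with
  the session baseline drawn once per session (mean 2000 au, SD 50 au),
  AR(1) noise of marginal SD 100 au and coefficient 0.9 (vectorised via a
  linear filter), and additive offsets in baseline-SD units per AOI
  (default AGR −0.3 z, reproducing the relative pupil constriction seen when
  viewing AGR images). Blinks are Poisson (0.1 s⁻¹, 100 ms) zero-pupil gaps
  with invalidated positions.
- **Randomness.** One root seed; trial k of a session draws from
  `default_rng([config_seed, plan_seed, k])`, so any trial is reproducible
  in isolation and whole runs are bit-reproducible.
- **Geometry.** 8° × 8° image windows centred ±8° horizontally — plumbing
  defaults, since window geometry is not part of what the analysis estimates.

What the generator does **not** model: smooth pursuit, microsaccades,
saccade kinematics beyond a constant 40 ms linear transit, image-content
saliency beyond the ROI mixture, pupil light/accommodation responses, or
drift within fixations. Passing recovery tests therefore demonstrate that
the pipeline measures what the generative model defines — not that real
tracker noise, pursuit, or drift would leave the detector unbiased.

## Study design objects

The default roster mirrors a two-subject colony design: 6 female and 9 male
stimulus monkeys in two rooms, 20 face/AGR image pairs each; sessions present
every image exactly once (120 female / 180 male trials), with face side
assigned fairly and independently per trial. Ages are synthetic but span the
stated 6–23-year range on both sides of the age boundary. Identity classes:
*young* is under 9 years, 9 and over is *old* (the boundary rule that
partitions all ages); *familiar* means co-housed with the subjects.

## Statistics

All tests are two-tailed. Signed-rank: zeros dropped, midranks for ties;
exact two-tailed p for n ≤ 25 from the generating-function distribution of
the positive-rank sum over all 2ⁿ sign patterns (doubled ranks keep the
support integral); otherwise a normal approximation with the tie-exact
variance Σr²/4 and a 0.5 continuity correction. Rank-sum: Mann-Whitney U
with exact enumeration of rank assignments when the smaller group has ≤ 10
observations, else the tie-corrected, continuity-corrected normal
approximation. χ² tests are Pearson (no Yates correction), refusing expected
counts under 1. Factorial ANOVA uses type-II sums of squares — each effect
adjusted for all terms not containing it — computed by comparing nested
least-squares fits on dummy-coded designs; type II keeps main effects stable
in near-balanced designs, and the implementation is cross-checked against an
independent reference in the tests. Tukey's HSD uses the studentized-range
distribution with the Tukey-Kramer standard error for unequal group sizes
(k = 2 degenerates to the plain t-test). Two-tailed exact p-values are
`min(1, 2·min(P(T ≤ t), P(T ≥ t)))`.

Type-I calibration is tested at α = 0.05 over 10⁴ null replicates per test;
discrete tests (rank tests, χ²) attain sizes slightly off 0.05, so the
replicate sizes (n = 20 signed-rank, 30/30 rank-sum, 200 Bernoulli trials)
are chosen where the attainable size lies inside 5% ± 1%.

## Pipeline, determinism, problem sizes

The CLI stages (simulate, detect, metrics, pupil, heatmap, stats, report)
communicate through plain-text artefacts (TSV sample logs, JSON layouts,
CSV tables with a seed + config-hash provenance line); repeated runs with
the same config and seed are byte-identical. `simulate_and_analyze` runs the
same computation in memory for recovery studies.

Test-suite problem sizes are study-scale where the quantity demands it
(9 × 120 trials for pAGR and first-gaze recovery, ≥ 2000 trials for the
decorrelation property, 10⁵ draws for duration calibration, 10⁴ replicates
for test calibration) and small elsewhere.

## Known limitations

- I-DT over-segments under strong per-sample noise (see above); a
  velocity-based detector is deliberately out of scope.
- Baseline pupil statistics pool all pre-stimulus segments of a session
  (per-trial baselining is available but noisy for 500 ms windows).
- The heat maps bin samples, not fixations, and pool left/right
  presentations in window coordinates.
- ANOVA assumes homoscedastic normal errors; it is applied here to counts
  and proportions exactly as the field's standard practice does, not because
  those quantities are Gaussian.
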