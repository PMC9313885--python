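# Methods

`neophobia` re-implements, end to end, the analysis chain of a two-choice
neophobia assay for larval zebrafish (*Danio rerio*): a single larva swims
for 10 minutes in a small rectangular tank containing a novel stimulus on
one side, and the degree to which it avoids that stimulus is read out from
video as an anxiety-like phenotype.  The package covers four stages —
synthetic data generation, video tracking, behavioral scoring, and
statistics — each usable on its own.

## Assay geometries

* **Novel object** (`mode="object"`): a 70 × 50 mm arena with two
  20-mm-diameter circular choice sectors, one centred in each half of the
  tank.  The stimulus sector holds the object (a 7-mm cone, ≈213% of the
  3.29-mm mean larval body length); the other circle is its mirror image
  and stays empty.
* **Novel odor** (`mode="odor"`): a 150 × 50 mm arena divided lengthwise
  into three equal sections; one end section carries the odor source, the
  opposite end is the control, the middle counts as neither.

Circle membership is boundary-inclusive Euclidean distance; the thirds are
half-open intervals `[start, end)` with the final third closed, so the three
sections partition the length exactly and no frame is double-counted.
Stimulus side (left/right counterbalancing) is arena metadata; every metric
is expressed in stimulus/empty terms.

## Synthetic trajectories

The generator is a two-state (move/pause) correlated random walk at 25
frames/s, with reflective walls:

* **Heading**: wrapped-normal perturbation per step with mean resultant
  length `heading_persistence` (default 0.98, i.e. a heading decorrelation
  time of ≈2 s — the straight beat-and-glide cruising regime), plus a
  deterministic bias `|attraction|·sin(bearing_to_target − heading)`.
  Positive attraction targets the stimulus-sector centre; negative
  attraction targets the opposite (empty/control) sector, because avoidance
  in this assay is a retreat to the far side of the tank.  This makes the
  expected preference rise monotonically through 50% as the coefficient
  crosses zero, over its whole range.
* **Step length**: gamma-distributed (shape 2) with mean
  `mean_speed/fps`; default mean speed 8 mm/s ≈ 2.4 body lengths/s.
  Inside the stimulus sector the mean step is multiplied by
  `stimulus_speed_factor`, giving the velocity analysis a recoverable
  per-sector signal.
* **Pauses**: a two-state Markov chain (`p_pause = 0.02`,
  `p_resume = 0.10` per step, started from its stationary distribution)
  produces immobility bouts of ≈0.4 s occupying about a sixth of the trial;
  paused frames repeat the previous position exactly.
* **Thigmotaxis trait**: each subject draws a wall-ward heading bias from a
  gamma distribution (shape 2, mean 0.05).  This is the generator's model
  of persistent individual variation: strongly wall-bound larvae rarely
  enter the interior choice sectors (few, short visits — small totals, noisy
  preference), weakly wall-bound larvae sample them often.  The trait scale
  was chosen so that (i) the spread of per-subject choice-sector totals over
  a 10-min trial is as wide as the assay reports (tens to ~200 s), and
  (ii) the variance of the arcsine-transformed preference scales inversely
  with the total (measured log–log slope −1.0) — precisely the
  binomial-error regime that motivates weighting the preference analysis by
  those totals.  Without such a trait (all subjects exchangeable) the
  totals vary only by chance, the inverse-variance relation disappears, and
  the weighted F-test is measurably anticonservative; with it, the null
  rejection rate of the full chain is at the nominal 5% level.

All randomness flows from one seeded NumPy generator; per-walker streams are
seeded from it, so every output bit is a pure function of the seed.  The
per-step update runs in a compiled (numba) kernel; a cohort of 120 subjects
at full duration simulates in well under a second, which is what makes
1000-replicate calibration studies routine.

A cohort design maps each (treatment, age) cell to an attraction
coefficient (and optionally a stimulus-speed factor), with n subjects per
cell (default 20, 2 treatments × 3 ages — the assay's layout).

### What the generator does *not* model

Beat-and-glide kinematic microstructure, odor plume diffusion, body growth
across ages, and any direct dependence of locomotion on age or treatment
other than what a design assigns.  Passing tests therefore show that the
pipeline recovers what the generative model puts in — they cannot certify
tracker or model behavior on real video beyond the features emulated here
(dark blob, static background, additive sensor noise).

## Rendering and tracking

`render_video` draws each trajectory point as a dark ellipse (default
3.29 mm long, aspect 0.35) on a light static background at 4 px/mm, with
optional stimulus object and additive Gaussian noise; the background
(including the stimulus) is identical in every frame.

The tracker mirrors a standard offline pipeline: per-pixel temporal median
of ≤200 uniformly spaced frames as the background (robust while the larva
occupies any pixel in <50% of sampled frames); signed difference
`background − frame` so only features darker than the background survive;
binarization at a fixed threshold or, by default, Otsu's threshold on pooled
difference images of a frame subsample (floored at 1 gray level); largest
connected component with area ≥ `min_area` (default 25% of the expected
blob area); centroid in continuous pixels, origin top-left, x rightward,
y downward.  Detection gaps of ≤ `gap_max` frames (default 5) are bridged
linearly and flagged `interpolated`; longer gaps stay missing and excluded
from all downstream sums; >50% undetected frames is a tracking failure, not
a silent degradation.  Pixel coordinates are calibrated to mm by
`px_per_mm` (or from an arena landmark length via `calibrate`).

On its own renders the tracker recovers centroids with RMSE ≤1 px
noise-free and ≤2 px at 5 gray levels of noise, and is invariant to static
objects in the scene.

## Behavioral endpoints

Per subject: time in each choice sector (each labelled frame contributes
1/fps s); approaches = entries that persist ≥ `min_dwell` frames (default
2, to debounce boundary jitter; equivalently maximal inside-runs of that
length); mean swimming speed per sector over steps *starting* in the sector
(interpolated frames excluded; undefined sectors are NaN, never fabricated);
activity fraction = share of steps faster than `speed_floor` (default
1 mm/s).

Exclusion rules, applied as flags (records are never deleted): object test —
activity fraction < 5% → `immobility`; odor test — combined end-section
time < 5% of the trial → `nonchooser`.  The odor rule reads "both sections"
as the combined total, consistent with nonchoosers being subjects that stay
in the central section >95% of the time.

Preference index: `t_stimulus/(t_stimulus + t_empty) × 100` (and the
analogous approach percentage), with the raw totals kept as analysis
weights.  Equal occupancy gives exactly the 50% chance level.

## Statistics

* **Weighted ANCOVA**: the preference percentage is arcsine-square-root
  transformed and fitted by weighted least squares with sequential
  (entry-order) sums of squares — age (numeric, dpf), then treatment, then
  their interaction; an experiment factor can be appended for pooled
  analyses.  Weights are the raw totals; F and p are invariant to
  rescaling all weights by a positive constant, so normalisation is
  immaterial.  The sums-of-squares type is sequential because that is the
  default of the R modelling stack this analysis chain descends from; it is
  configurable through the term order.
* **Post-hoc weighted t-tests**: one-term WLS fits on two-group subsets;
  t² equals the one-way weighted F exactly, and with equal weights the test
  reduces to the pooled-variance two-sample t.
* **Velocity mixed model**: log velocity with two observations per subject
  and a subject random intercept, fixed effects sector × treatment × age.
  The between/within variance ratio is estimated by numerically minimising
  the profiled REML criterion (for this balanced design the optimum has the
  classical closed form MS_between/MS_within − ½, which the optimiser
  reproduces).  With two observations per subject the design splits into
  orthogonal strata: subject means carry age, treatment and age × treatment
  (denominator df = subjects − 4), subject differences carry sector and all
  sector interactions (same df) — for the assay's 116 included subjects
  both give 112, matching the reported degrees of freedom.  When the REML
  estimate of the between-subject variance hits the zero boundary the
  random intercept vanishes and the model is refitted as pooled OLS with a
  sequential ANOVA (residual df = N − 8); in that limit the F table agrees
  exactly with a fixed-effects ANOVA.
* **Nonchooser counts**: Pearson chi-square without continuity correction
  (the 21/120 vs 4/120 contrast gives X²₁ = 12.904), and a binomial GLM
  likelihood-ratio test of an age-factor (or treatment) model against the
  intercept-only null on grouped counts.  A plain age-factor LR on the
  published per-age counts (14, 4, 3 of 40) gives ≈12.18 with 2 df; the
  package reports this LR and the Pearson variant and does not claim to
  reproduce any other published value for that model, whose exact
  specification is ambiguous.  Complete separation is reported as the
  boundary fit.
* **Outlier screening**: externally studentized residuals with |t| > 3 are
  flagged; removal only ever happens on explicit request.  This is a
  reproducible stand-in for visual residual inspection, not a
  reconstruction of it.

All tests are two-sided at α = 0.05 with no multiplicity correction,
matching the analysis conventions of the assay.

## Calibration results the test suite enforces

At the defaults above and the assay's own scale (10-min trials, 25 fps,
n = 20 per cell, 2 treatments × 3 ages):

* Null cohorts (attraction 0 everywhere): the weighted-ANCOVA
  treatment-term rejection rate over 1000 replicate cohorts lies in
  [0.03, 0.07] at α = 0.05.  This check runs at the full 600-s duration
  deliberately: shorter trials leave the sector totals dominated by a few
  long visits, the inverse-variance premise of the weighting degrades, and
  the test measurably over-rejects.
* Effect recovery: with enrichment-linked attraction only at 14 and
  21 dpf, the age × treatment interaction is significant in ≥80% of 200
  replicates, with the post-hoc pattern (difference at 14/21, none at
  7 dpf) in the majority.  The effect size (attraction 0.02) was fixed by a
  pilot dose–response at the assay duration; notably, at n = 20 per cell
  the interaction test only reaches that power for a large separation
  (affected-cell weighted preference ≈88% vs 50% chance) — moderate doses
  (60–70%) load mostly on the treatment main effect because the
  (0, δ, δ)-across-ages pattern is nearly flat in its age-linear component.

## Numerical choices and degenerate inputs

Sequential SS computed by incremental least squares with rank checks
(an aliased term raises an error naming it).  Zero residual variance in a
stratum yields F = 0 for zero-SS terms rather than NaN.  Proportions are
clipped to [0, 1] only against floating-point overshoot of the percentage
arithmetic before the arcsine transform.  A preference with zero total time
or approaches is an explicit undefined-preference error.  Simulated steps
are capped at 0.45 × the smaller arena dimension so a single wall
reflection always suffices (the cap sits ~20 standard deviations above the
mean step).  Known limitation: per-walker RNG streams are seeded with
31-bit integers drawn from the master generator, so two walkers in a very
large study could, with vanishing probability, share a stream.
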