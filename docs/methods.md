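# Methods

This note documents the models, defaults, and numerical choices behind
`ieegface`, and what the synthetic validation does and does not
establish about real intracranial data.

## Paradigm and data model

A session consists of blocks of 108 trials: fixation (uniform
500–800 ms) → neutral direct-gaze face (Face 1, uniform 400–600 ms; a
fixed 500 ms variant is available via `timing_jitter=False`) → the same
face turned happy/fearful with direct/averted gaze (Face 2) → a lateral
checkerboard target after 300/350/400/450 ms, omitted on the 12 catch
trials per block. Cells are exactly balanced: 18 trials per
emotion × gaze cell, 2 of them catch, so gaze changes are equally
frequent under both emotions. Trials are laid end to end with a 1 s
response window and 1 s inter-trial interval; absolute event times are
part of the design table so simulation and epoching share one clock.

Recordings are modeled as monopolar contacts along depth-electrode
shafts (index 1 = deepest; 5 or 10 mm spacing; 400 or 1024 Hz). A
bipolar *site* is deeper − shallower of two adjacent retained contacts,
located at their coordinate midpoint; this suppresses volume-conducted
common signals and emphasizes local generators. Hemisphere follows the
sign of MNI *x* (x < 0 → left; a site exactly at x = 0 is assigned right
as a deterministic tie-break).

## Synthetic forward model

Each ROI carries a component set of Gaussian-envelope deflections
(label, peak latency ms, signed amplitude, envelope SD ms). Defaults
(amplitudes in μV against a 10 μV pink-noise background, α = 1, plus
2 μV white noise):

| ROI | Face 1 | Face 2 |
|-----|--------|--------|
| IOC | N200 125 ms (−55), P250 225 ms (+20) | N200 155 ms (−60), P250 255 ms (+18) |
| FC  | P100 95 ms (+12), N200 150 ms (−50), P250 245 ms (+18) | P100, N200 190 ms (−52) |
| ITC | P100 95 ms (+10), N200 150 ms (−45), P250 245 ms (+15) | P100, N200 190 ms (−50) |
| STC | slow wave 300 ms (−28, SD 70 ms) | N200 190 ms (−45) |

These encode the qualitative structure the analysis is meant to
recover: IOC earliest, ITC/FC together later, STC slowest for face
onset but sharp for the social-cue change. Absolute z-scale amplitudes
are a package choice (the per-component scales are not published
quantities); with the default noise they yield trial-averaged peaks of
roughly |z| = 3–6 at generator-adjacent sites. Peak latencies are
placed well inside the per-ROI peak-search windows of the ERP analysis
(e.g. FC Face 1 at 150 ms because its search window is 0–170 ms): a
peak planted at a window edge biases the truncated argmax and is not a
test of the estimator.

Each shaft has one planted generator between contacts `flip_after` and
`flip_after + 1` (default 3/4): signs flip there (polarity reversal)
and the field gain decays as exp(−d/12 mm) with distance along the
shaft, so the straddling bipolar pair sees ~2× the monopolar amplitude
while more distant pairs see graded, partially cancelled responses —
without the decay, identical same-sign neighbours would cancel exactly
and each shaft would yield a single active site, which real recordings
do not show.

Condition effects are amplitude/latency deltas applied to the dominant
Face-2 deflection; the default plants a strong gaze effect in STC
(−20 μV for averted vs. direct) and small (±4–5 μV) gaze/emotion
modulations elsewhere, mirroring the STC gaze dominance the condition
analysis is designed to detect. Artifacts are injected per trial at
configurable rates: ±850 μV excursions (caught by the voltage
threshold), 350 μV spike transients, and 200 μV blink templates on a
designated scalp channel; all planted trials are recorded in the
ground truth.

The fast path `simulate_site_epochs` emits already-epoched,
baseline-normalized single-site data with white unit noise for
large-count statistical simulations. For experiments that estimate
*peak latencies* of averaged waveforms the generator instead uses
low-passed noise (Gaussian-smoothed, ~10 ms): the pipeline's 40 Hz
low-pass means real averaged ERPs never carry white noise, and with
white per-sample noise peak picking degenerates into an extreme-value
problem whose variability the jackknife cannot track.

What the generator does **not** emulate: volume conduction and
realistic head geometry, seizure dynamics and true interictal activity
(spikes are stylized transients), inter-patient anatomical variability,
trial-to-trial latency jitter of components, and real tractography
(streamlines are scattered straight bundles). Passing tests therefore
demonstrate correctness of the *procedures* under the planted
statistical structure, not robustness to every pathology of clinical
data.

## Preprocessing

Order: high-pass + band-stops → long epochs → artifact rejection →
behavioral exclusions → 40 Hz low-pass → downsample → bipolar →
z-score, stamped into a provenance list. Filters are Butterworth in
second-order sections, applied forward–backward (zero phase) to
preserve peak latencies; "order 4" band-stops follow the
band-pass/stop convention in which the design order applies per edge.
Downsampling 1024 → 400 Hz uses polyphase resampling at 25/64 (output
length ⌈n·25/64⌉); 400 Hz input passes through bit-identical.

Rejection rules: ±750 μV anywhere in the long epoch on any retained
in-brain contact; spike transients (sample-to-sample jump > 150 μV)
and blinks (> 100 μV on the designated scalp channel) only within
[Face 1 − 500 ms, target + 300 ms]. The transient and blink detector
thresholds are package parameters, not published values — the original
review was partly visual/interactive, which a pipeline cannot
reproduce. Behavioral order matters: pre-target presses are removed
first, then misses/false alarms, then the ±3 SD reaction-time trim
computed from the remaining target trials; finally any block retaining
under half its designed trials is dropped whole. The first triggered
reason per trial is the one logged.

Epochs locked to a face event cover [−100, +400] ms; z-scoring uses
the half-open [−100, 0) ms baseline per trial and site with the sample
SD (ddof = 1), so the onset sample never contaminates the baseline. A
zero-SD baseline flags the trial `degenerate_baseline` and drops it.
Catch trials, which have no target, anchor their epoch end at
Face 2 + max SOA + 1 s so windows stay comparable.

## Responsiveness testing

The |Z| > 1 screen is strict (exceeding means >) and runs on the
trial-averaged response in 0–400 ms. The cluster test forms clusters
from pointwise one-sample *t* values beyond the two-sided α = 0.05
quantile of t(n−1); same-sign contiguous samples form a cluster with
mass Σt (opposite signs never merge). The null is the distribution of
the maximum |mass| under random whole-trial sign flips (default 1000
draws, seeded); p = (1 + #{null ≥ observed})/(1 + n_perm) is never
zero, and an exhaustive 2ⁿ enumeration mode (n ≤ 20) serves as the
exactness oracle. Bonferroni correction divides 0.05 by the number of
*screened-in* sites in the same ROI × hemisphere.

## ERP morphology, amplitude, latency

Slices A–E are half-open 10 mm bins over y ∈ [−81, −31), F is
y ≥ −31, IOC is pooled; sites posterior to −81 go to A with a warning.
Rectification finds the peak of the across-site mean of |ERP| in the
ROI's broad window, computes each site's mean in ±25 ms around it, and
flips positive-mean sites, making the group mean's dominant deflection
negative; the procedure is invariant to flipping any input site.
Amplitude effect sizes are one-sample d = μ/σ of trialwise means in
peak ± 50 ms on the un-rectified signal, reported as |d| with
0.2/0.5/0.8 bands; windows clip at epoch edges with a warning.

Peak latency defaults to the parabolic vertex through the discrete
extremum and its neighbours. A purely discrete argmax is quantized to
the 2.5 ms grid, which destabilizes leave-one-out differences and,
empirically in this package's coverage experiment, pushes jackknife CI
coverage below nominal; the sub-sample refinement makes the statistic
smooth in the data, which the jackknife variance argument requires.
`refine="discrete"` restores the plain argmax (ties → earliest).

The jackknife SD uses the √((n−1)/n Σ(θᵢ−θ̄)²) inflation — for a
linear statistic it equals the analytic SEM exactly, which the tests
assert to machine precision. Pairwise ROI comparisons Bonferroni-divide
0.05 by the number of pairs actually run (6 for four ROIs; a single
pair is uncorrected). The omnibus ANOVA retransforms leave-one-out
values to pseudo individual scores yᵢⱼ = nⱼθ̄ⱼ − (nⱼ−1)θᵢⱼ before a
standard one-way ANOVA; for equal group sizes this is identical to
dividing the naive F by (n−1)², and it remains well defined for
unequal sizes.

## Condition effects

The 2 × 2 ANOVA treats emotion (happy/fearful) and gaze
(direct/averted, pooling left+right) as between-trial factors, with
Type II sums of squares so mildly unequal cell counts are handled
(F tested against the full-model MSE, df = n − 4). Cluster formation
thresholds F at its pointwise α = 0.05 quantile; mass is ΣF. Null
distributions: main effects permute that factor's labels; the
interaction permutes one factor's labels within levels of the other
(both margins preserved) — an approximate restricted scheme, adequate
for the type-I behaviour the suite verifies but not exact under strong
main effects. Effect sizes are two-sample pooled-SD d over the
largest-mass cluster's window; |d| is reported because bipolar polarity
is arbitrary.

## Tract endpoints and overlap

Voxels are 1 mm half-open cubes (membership = floor of the mm
coordinate relative to the grid origin). Outlier cleaning removes
streamlines more than 4 SD above the mean centroid distance or away
from the mean length; identical streamlines (zero SD) remove nothing.
Reorientation minimizes endpoint distance to a reference pair — per
set by default, and shared across subjects of a tract in the grouped
pipeline, since the first/last collection assignment is otherwise
arbitrary per subject and group support would split between the two
ends. Endpoint counts are smoothed with a uniform spherical kernel
(radius 3 mm, 123 voxels, normalized to preserve total mass;
radius 0 = no smoothing).

The per-subject density threshold of 0.01 applies to the raw smoothed
counts: with the mass-preserving kernel it means at least two
endpoints within the kernel radius of a voxel. Thresholding the
density *normalized* by the subject's total endpoint mass is also
implemented (`normalized=True`) but cannot be used with 0.01 — the
same kernel caps normalized density at 1/123 ≈ 0.008 per voxel, so
every mask would be empty; this is why raw is the default. Group masks
count subjects whose binarized density covers a voxel; overlap entries
are the proportion of a (ROI, response-class) site group inside voxels
supported by ≥ 100 subjects, sites outside the grid counting as
not-inside with a warning, and all-zero tract columns dropped (and
logged). Overlap is monotonically non-increasing in the validity
threshold.

## Validation experiments and problem sizes

`ieegface.experiments` (used by the tests and `scripts/acceptance.py`)
runs: Monte Carlo vs. exhaustive enumeration at 10 trials and 5000
draws; type-I error over 1000 null sites (20 trials one-sample;
10 trials/cell factorial; 200 permutations each); one-sample d = 0.8
recovery over 200 replicates of 100 trials per gaze condition;
jackknife-vs-SEM identity; 95 % CI coverage of a 30 ms latency shift
over 200 simulations of 10 sites per condition; the latency-ordering
experiment over 100 runs; and exact endpoint-overlap constructions
with 120 (or 99) subjects of 30 streamlines. These sizes keep the full
validation under a minute while leaving Monte Carlo error comfortably
inside each check's tolerance.

## Known limitations

* The blink/transient detectors are threshold rules standing in for an
  interactive review; their parameters are conventions, not published
  values.
* The interaction permutation scheme is approximate (see above).
* The jackknife CI for peak latencies assumes the across-site
  average has a well-defined single peak inside the search window;
  flat waveforms raise rather than guess.
* Latency inference treats site sets as independent samples; the
  supplementary mixed-effects modelling of patient-level clustering is
  out of scope.
* Tract endpoints are analysed in MNI space as given; registration,
  tracking, and tract segmentation are upstream of this package.
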