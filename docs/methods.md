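# Methods

## Track motion model and classifier

### Classification rules

Input tracks are ordered (frame, x) samples of single organelles along an
axon, with contiguous frames. The classifier works on inter-frame
intervals:

1. **Movement flag**: interval i is "movement" iff |x[i+1] − x[i]| >
   `movement_eps_px` (default 0.5 px). With integer-pixel tracker output
   this is exactly the changed/stayed-the-same comparison; the epsilon only
   matters for sub-pixel float imports.
2. **Segmentation**: maximal constant-flag blocks are found; moving blocks
   are split at displacement-sign reversals so every run has one
   direction (the split assigns the reversal boundary to the later
   subinterval). Moving (sub)blocks of ≥ `min_run_frames` (5) intervals
   are runs; non-moving blocks of ≥ `min_pause_frames` (5) are pauses;
   everything else is oscillation. Segments tile the track exactly.
3. **Metrics**: run distance = Σ|Δx| over the run × `pixel_size_um`
   (0.175); run speed = distance / duration. Pause durations are reported
   only for mobile tracks (those with ≥ 1 run). Net displacement =
   (x_last − x_first) × pixel size, sign-mapped to direction by the ROI's
   `anterograde_sign`; the anterograde/retrograde/none class requires
   mobility and |Δx| ≥ `net_disp_threshold_px` (5 px = 0.875 µm).
   Tracks shorter than `min_track_frames` (20) are rejected with a logged
   reason, not interpolated — silent gap-filling would bias pause
   statistics.

Per-track directional speed is the unweighted mean of per-run mean speeds
(configurable to duration-weighted); per-axon aggregates are means over
the axon's tracks (pause aggregates over mobile tracks with pauses,
directional aggregates over tracks with runs in that direction), because
group-level statistics treat the axon as the experimental unit.

### Synthetic trajectory generator

Each particle is stationary with probability `p_stationary` (then its
position is constant) or mobile. Mobile tracks alternate pause and run
blocks until the 180-frame window is filled:

* Run speed and length are drawn per direction (probability
  `p_retrograde_run` of a retrograde run) from log-normal distributions
  parameterized by their **median** — the wild-type preset uses the
  reported cohort medians directly (anterograde 5.88 µm at 0.43 µm/s,
  retrograde 8.71 µm at 0.48 µm/s; 56% stationary; pauses median 16.4 s)
  — with log-sd 0.25, a modest within-genotype spread chosen so the
  distribution mean stays within a few percent of its median. Speeds are
  resampled to at least 1 px/frame so the rounded track moves every frame
  of a run; run durations (length/speed, rounded to frames) are resampled
  to ≥ 5 frames, the detection floor below which a "run" would be
  unclassifiable ground truth.
* Pauses are drawn from a log-normal (median 16.4 s for wild type) with
  support ≥ 5 s.
* Oscillation episodes are 1–4 frames of alternating ±1 px jitter,
  inserted immediately before a run with the episode's final jitter sign
  opposite to the run's sign. This is the minimal motion below both
  cutoffs, and the sign constraint guarantees the episode never merges
  with an adjacent run, so classifier labels equal ground-truth labels
  exactly on noiseless tracks (a tested invariant).
* Positions are simulated continuously and rounded to the integer pixel
  grid, matching tracker output.
* Blocks cut by the end of the window are kept as what they became: a cut
  run of ≥ 5 frames remains a (shorter) run, smaller remnants become
  oscillation. A finite movie imposes the same censoring on real data, so
  the generator reproduces it rather than avoiding it; its net effect on
  recovered medians is within the stated recovery tolerances.

What the generator does **not** emulate: photophysics (bleaching,
blinking), detection/tracking errors, crossing trajectories, sub-pixel
localization noise, or spatial interactions between organelles. Passing
round-trip tests therefore validates the measurement pipeline's logic and
calibration handling, not robustness to tracker failure modes.

## Kymograph extraction

Polylines are resampled at uniform arc length (1 px step, endpoints
preserved, n = round(L)+1 samples); tangents are central differences of
the sampled points, making the normal field symmetric under vertex-order
reversal. At each sample the stack is probed at `width_px` (default 10)
centered offsets along the normal, bilinearly interpolated (a
nearest-neighbor mode exists for exact-arithmetic tests), and reduced by
max (default; appropriate for sparse punctate signal) or mean. The
reducer and interpolation are configurable because reslicing tools vary
in both. Anterograde is increasing arc-length coordinate; the ROI carries
a `soma_at_start` flag because direction comes from chamber geometry, not
from the image.

## AIS structure

**Autocorrelation** is computed on the mean-subtracted profile with the
biased estimator (lag-k sum divided into the lag-0 sum), so the curve is
exactly 1 at lag 0 and bounded by ±1. The period estimate is the lag of
the first side peak with prominence ≥ 0.3 (scipy peak prominence); the
threshold is set so that white-noise profiles of the typical length
(~330 px) essentially never produce a period while 10%-noise lattice
profiles always do. A curve without such a peak yields a missing value.

The synthetic MPS generator snaps the lattice constant to the sampling
grid (190 nm at 30 nm/px → 6 px = 180 nm), so noiseless profiles have
exactly periodic maxima and the recovered period is grid-deterministic;
estimates are compared to the nominal spacing within one pixel (30 nm).

**Patch detection**: Gaussian smooth (σ = 1 px) → threshold at
background + `pa_thre` × (ROI max − background), with background the 10th
percentile of ROI intensities (robust to sparse bright structure) →
8-connected components → discard components smaller than `area_thre` ×
the median candidate area. The two thresholds keep their conventional
defaults (0.6, 0.7); their precise semantics are this package's own,
since the upstream detection script's internals are not published, and
both are configurable.

**AIS length**: rolling-mean smoothing (default 1 µm), background
subtraction (10th percentile), normalization to the maximum, and the
outermost crossings of `threshold_fraction` (default 0.33) located by
linear interpolation between samples. The 0.33 fraction follows common
practice for marker-profile AIS length criteria and is configurable; the
measure is invariant to positive rescaling of the profile. A profile
never exceeding the threshold returns a flagged no-AIS result.

## Colocalization

Detection runs on channel A only; per-channel background is the median
intensity outside all detected footprints; integrated density is the
background-subtracted sum over the footprint, measured identically in
both channels. The summary regression is OLS of B on A (matching the
y = f(x) orientation with the detection channel on x) plus Spearman's
correlation with midrank ties.

## Statistics

Normality is screened per group with D'Agostino–Pearson (groups with
n < 8, where the test is undefined, route to the nonparametric branch).
Two groups: t-test or Mann–Whitney; three or more: one-way ANOVA or
Kruskal–Wallis with Dunn's post-hoc. Dunn's test is computed from the
pooled ranking: z = (R̄_i − R̄_j)/√((N(N+1)/12 − ΣT/(12(N−1)))(1/n_i+1/n_j)),
two-sided, with Holm (default), Bonferroni, or no adjustment, and either
all-pairs or many-to-one comparisons against a reference group. Median
CIs use the binomial order-statistic interval [x_(j), x_(n+1−j)] with the
largest j keeping coverage ≥ 95%; samples too small for any such interval
fall back to a seeded bootstrap. Fully constant data short-circuits to a
degenerate "nothing to test" result instead of a spurious p-value. A
two-factor ANOVA helper (statsmodels) covers percentage outcomes crossed
by genotype and culture.

## Problem sizes and numerical choices

Round-trip validation uses cohorts of 100 axons × 20 tracks × 180 frames,
comfortably larger than typical per-group axon counts in such
experiments, so cohort medians of per-axon means estimate the generative
parameters to a few percent. Segmentation is cross-checked against a
brute-force rule enumerator on 10⁴ random tracks. Periodicity recovery is
assessed over 100 seeded replicates per condition. All randomness flows
through `numpy.random.default_rng` seeds; every generator called twice
with the same arguments is bit-identical.

## Known limitations

* The run/pause cutoffs make measured quantities discrete at the frame
  and pixel scale; quantities near a cutoff (e.g. 5-frame runs) are
  sensitive to single-pixel noise in real tracker output.
* Oscillation is defined only negatively (below both cutoffs), so the
  generator's ±1 px jitter is one of many motions consistent with it.
* Patch-detection semantics (`pa_thre`/`area_thre`) are a documented
  stand-in for an unpublished reference script; absolute patch areas
  should only be compared within one parameterization.
* The AIS-length 0.33 criterion is a convention; reported lengths shift
  systematically with the threshold and smoothing width.
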