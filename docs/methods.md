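# Methods

This note records the models, conventions and numerical choices behind
`larvakin`, what the synthetic-behavior generator does and does not emulate,
and the design decisions taken where the underlying measurement procedure is
genuinely open.

## Trajectory model (synthetic_behavior)

Larval swimming is modeled as burst-and-glide: an alternating sequence of
rests and bouts whose durations are drawn from **discrete truncated power
laws** on the integer frame lattice `{min_duration·fps, …, duration·fps}`
(durations are inherently frame-quantized, so a discrete support is the
natural choice; sampling is inverse-CDF on the normalized lattice weights
`x^(−k)`). During a bout the larva takes one step per frame:

- step length = speed / frame rate, with per-frame speeds lognormal around
  `mean_speed` at coefficient of variation `speed_cv` (mean-one
  multiplicative noise);
- heading performs a persistent random walk: per-frame turn
  ~ N(0, ((1 − heading_persistence)·π)²);
- within 1 mm of the wall the heading is pulled toward the nearer wall
  tangent with weight `min(1, wall_affinity · (1 − d/1 mm))` — the simplest
  mechanism that produces wall-following at high affinity and
  wall-indifference at zero;
- steps that would leave the well reflect specularly off the circular wall
  (position folded, radial velocity component negated). Positions are kept
  strictly inside the wall with a 0.01 mm margin.

Rests are perfectly stationary by default; `rest_jitter` (mm, default 0)
adds Gaussian positional noise to stress-test the activity threshold.
Recordings start at an area-uniform position with uniform heading, and the
first interval's type is chosen at random.

Each generated trajectory carries its ground truth (`meta`): the interval
list, true activity percentage and realized mean bout speed, which the
round-trip tests compare against.

### Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| frame_rate | 30 | Hz | open-field recording rate |
| duration | 900 | s | 15-min session |
| k_rest / k_bout | 2.0 / 1.9 | — | see below |
| min_duration | 0.1 | s | shortest resolvable bout/rest; one frame (the lattice floor) is allowed explicitly |
| mean_speed | 18.9 | mm/s | wild-type median bout velocity |
| speed_cv | 0.25 | — | moderate within-bout speed variability |
| heading_persistence | 0.85 | — | bouts are locally fairly straight |
| wall_affinity | 0 | — | neutral base model; presets set it |

The exponent defaults deserve a comment. Published rest-duration exponents
for this assay are far below 1; on a pure truncated power law spanning the
whole recording such an exponent concentrates nearly all rest time in a few
recording-length pauses and drives activity to zero — irreconcilable with
the ~56% wild-type activity the same assay reports. Those shallow exponents
evidently come from a fitting convention applied to data that are not a pure
power law over the full support. The generator therefore defaults to
`k_rest = 2.0`, `k_bout = 1.9`, which put mean rests near 0.2 s and mean
bouts near 0.3 s and land median activity in the mid-50s percent — the
wild-type regime — while remaining genuinely heavy-tailed (per-larva
activity varies widely across seeds because single long rests are common,
as in real recordings). The published exponent values are still exercised
as recovery targets for the fitters.

### Phenotype presets

`wildtype_like()` (k_rest 2.0, k_bout 1.9, 18.9 mm/s, wall_affinity 0.3,
persistence 0.9) reproduces the wild-type medians: ~56% activity,
~19 mm/s, outer-ring occupancy ~80%, a flat wall-stay curve around 0.45.

`mutant_like()` (k_rest 1.6, k_bout 2.6, 9 mm/s, wall_affinity 0,
persistence 0.8) reproduces the full qualitative mutant phenotype
*ordering*: lower activity, velocity, outer-ring occupancy and rest
exponent; longer, more tortuous center-to-wall paths; and a wall-stay curve
that starts above the wild type's (slow, rest-dominated larvae linger where
they arrive) and falls below it within a few seconds. Reproducing that
stay-curve crossover inside this motion model forces a strongly hypoactive
mutant (~6% activity), which exaggerates the real mutant's deficit
(~26% activity); the preset trades median fidelity for qualitative
completeness, and any individual median can be matched instead by
overriding fields.

### What the generator does not emulate

Body posture and tail kinematics (the larva is a point), response latency,
bout-level speed profiles (acceleration/glide within a bout), interaction
between behavior and wall contact (bouts do not terminate on arrival at the
wall), multi-larva effects, illumination drift, or tracking artifacts other
than additive pixel noise. Tests passing on synthetic data therefore
validate the *analysis* — segmentation, fitting, event logic, geometry —
not the realism of any particular biological claim.

## Rendering and tracking

Frames are rendered as a dark Gaussian blob (depth 150 of a 200-intensity
background) at the mapped larva position; the mm↔px mapping is stored in a
JSON sidecar next to the zero-padded PNG frames and is the contract for real
data too. Tracking estimates a per-pixel median background over ≤200
uniformly subsampled frames, thresholds the signed difference image at
`threshold_sd` (default 5) robust spreads (1.4826 × MAD — blob pixels are
outliers by construction, so MAD reflects the noise floor; a 2-intensity
absolute floor guards the noiseless limit), keeps connected components of at
least `min_blob_area` px² inside the well mask, and returns the
intensity-weighted centroid of the largest. Detection gaps of at most
`max_gap_fill` frames (default 3) are linearly interpolated and flagged
`interpolated`; longer gaps are flagged `missing` and excluded downstream;
recordings with over 50% missed frames are rejected. Round-trip accuracy on
rendered stacks is ~0.05 px, well under the 0.5 px the kinematics tolerate.

## Segmentation and summary conventions

- movement threshold 0.1 mm/frame (≈3 mm/s at 30 Hz): above tracking jitter
  (<0.5 px ≈ 0.06 mm), far below real bout speeds (13–19 mm/s);
- merge_gap 2 frames, min_bout 2 frames; merging precedes the minimum-bout
  rule; the result is a strict alternation partitioning the recording;
- activity = active frames / total frames × 100; bout velocity averages
  per-frame displacement × frame rate over active frames and is *missing*
  (not zero) for a larva that never moves;
- a sample flagged missing never counts as movement; intervals are used in
  seconds; intervals touching the recording edges are kept (no censoring
  correction — negligible for hundreds of intervals).

## Power-law fitting

`Y = a·X^(−k)` is fitted with k reported positive for a decaying law.

- **loglog_regression** (default): durations are mapped to the frame
  lattice, histogrammed in logarithmically spaced bins whose edges are
  offset half a frame (so lattice points fall unambiguously inside bins),
  each bin count divided by the number of lattice durations it spans (the
  regressed quantity is then the probability mass per duration — the Y of
  the law — rather than the raw bin count, whose slope would be k − 1), and
  least-squares fitted in log10–log10. At least 5 occupied bins are
  required; sparse supports fall back to per-value counts, which makes
  exactly collinear toy inputs recover k exactly. Works for any k > 0,
  including the shallow k < 1 regime (normalizable only because the support
  is truncated).
- **discrete_mle**: maximizes the zeta likelihood
  `p(x) = x^(−k)/ζ(k, x_min)` by bounded scalar minimization on
  k ∈ (1, 25); unbiased to ±0.05 at n = 10⁵ but undefined for k ≤ 1.
- Both record `gof`, the Kolmogorov–Smirnov distance between the empirical
  CDF and a power law truncated to the observed range, and the convention
  used. Degenerate inputs (n < 10, single-valued support, non-positive
  durations) raise.

Per-larva fits require at least 10 intervals; larvae below that report no
fit and are counted, matching a median-across-larvae presentation.

## Thigmotaxis conventions

- zone classification is half-open: r < 4.5 mm is inner, the boundary circle
  itself is outer (the inner zone is an open disc covering exactly 36%);
- a recording that starts inside the wall band (or the center disc) counts
  as an event (or path start) at frame 0, flagged implicitly by its frame;
- wall-stay curves support two readings of "remaining next to the wall":
  **continuous residence** (distance < 1 mm at every frame up to t — the
  default) and **instantaneous presence** (distance < 1 mm at t,
  `instantaneous=True`). The instantaneous reading equals the
  per-timepoint integral of the distance-from-edge density map below 1 mm
  and is the one under which slow-but-wall-indifferent and
  fast-but-wall-attracted cohorts cross over; under continuous residence a
  fast swimmer's micro-excursions dominate the early hazard and no
  parameterization of this motion model reproduces the crossover;
- events whose 30 s follow-up window is truncated by the recording end are
  censored: they leave the denominator at their truncation point;
- per-timepoint group comparison uses a pooled two-proportion z-test
  (stayed vs departed) — a per-timepoint test on binary outcomes, for which
  a KS test would be inappropriate;
- distance-from-edge maps use 0.25 mm bins over a 30 s window at frame
  resolution, each time slice normalized over the events observed then;
- center-to-wall paths start at the *last* frame inside the center disc
  (radius 7.5·√0.05 ≈ 1.68 mm) before a wall contact and end at the first
  frame within 0.5 mm of the wall; the last-exit convention guarantees no
  intermediate disc re-entry; paths containing missing samples are skipped.
  For a straight radial swim the length is (7.5 − 0.5) − 7.5·√0.05
  ≈ 5.32 mm, which the geometry test checks to within one step.

## Embryo motor conventions

- contractions separated by less than `gap_threshold` (default 1.0 s,
  matching the minimum spacing used between stimuli; the grouping gap is
  exposed because no number is published) form one event; the event onset
  is its first contraction;
- C-bend detection thresholds default to 3σ (onset) and 1σ (return) of the
  trace's noise, with σ estimated as median(|deviation|)/0.6745 — the
  consistent scale estimate for symmetric noise on an absolute-deviation
  trace, robust while pulses occupy under half the samples. Candidate
  events need ≥2 consecutive supra-threshold samples (rejects single-sample
  noise spikes). Duration counts frames inclusively between the first
  supra-threshold sample and the first returned sample: onset detection is
  one sample late by construction while return detection is immediate, and
  the inclusive count centers the estimate (exact for noiseless half-sine
  pulses at 100 Hz). Bends that never return are flagged incomplete and
  excluded from duration statistics; after a stimulus marker only the first
  bend is scored.

## Group statistics

Quantiles use linear interpolation between order statistics (box statistics
differ across conventions, so the choice is declared). Whiskers are the most
extreme data points within the 1.5 IQR fences, not the fences. KS p-values
use the asymptotic two-sample formula by default (common practice at cohort
sizes of tens); an exact option exists for very small samples. No
multiple-testing correction is applied; the report records the number of
tests. The KS null-calibration check uses cohorts of 20 and 25: at small
*equal* sample sizes the discreteness of the KS statistic makes the
rejection rate lurch around the nominal level, while slightly unequal
cohorts (the norm in real group comparisons) smooth it; the empirical
type-I error at α = 0.05 lands near 0.04.

## Problem sizes used in tests and the acceptance script

Estimator-recovery checks use 10⁵ samples; the uniform-occupancy null uses
10⁶ positions; the tracking round trip uses a 1-minute, 30 Hz recording at
128 px; cohort comparisons use n = 20 larvae per group at 5 minutes each;
the KS null calibration uses 1000 replicates of 10 s recordings. These sizes
put Monte-Carlo error comfortably inside each check's tolerance while the
whole suite runs in well under a minute of compute.

## Known limitations

- The reflected persistent walk has an O(step-length) depletion layer at
  the wall (~1% deficit in the outermost 0.4 mm annulus), so strict
  area-uniformity at wall_affinity = 0 holds only to that precision.
- Log-log regression on heavy-tailed samples is mildly biased shallow
  (≈ −0.15 at k = 2.5, n = 10⁵) — the familiar tail-bin noise of histogram
  regression; the MLE does not share the bias and the two agree within 0.3
  on clean data.
- Per-larva exponent estimates from 5-minute recordings carry substantial
  variance; orderings across cohorts are reliable, absolute values less so.
- The generator's ground-truth activity and the displacement-threshold
  measurement can disagree by up to one frame per recording edge.
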