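# Methods

## Scope and model of the task

The package analyzes the place-item-matching phase of the Hidden Objects
Test (HOT): nine excursions from a central box inside a 3 × 4 m room, one per
hidden item, each returning to the box, with position tracked at a nominal
13 Hz. All analyses are planar; head orientation and controller pose are out
of scope. Timestamps are taken at face value (no resampling): every feature
and mining algorithm is timestamp-driven, so irregular sampling is accepted.

The room is modeled as a 3 × 3 grid of floor sections over the arena; five
sections are hiding places holding 1–2 of the nine items (loads 2/2/2/2/1).
The concrete item→section assignment in the packaged fixture is an arbitrary
fixed choice — scoring and mining depend only on the correctness bookkeeping,
never on which item sits where. World-frame tracker coordinates are treated
as opaque; all computations are translation-invariant, and a helper recenters
a walk on the arena center for plotting.

## HOT scoring

Five subtests with maxima 3, 9, 9, 9, 9 (total 39). Scoring rules:

* *prospective memory*: one point per executed instruction, order-free;
* *item free-recall*: order-free set intersection with the nine item names,
  matched after case-folding and whitespace-trimming (no fuzzy matching —
  clinical administration resolves synonyms before data entry); unknown
  names are ignored;
* *place free-recall*: marks are per **placement** (up to nine stickers); a
  hidden section earns `min(marks, items hidden there)` points. This is the
  only rule consistent with a 9-point maximum over five hiding sections;
* *item recognition*: nine 4-option trials; a choice outside the trial's
  options is a validation error, a wrong option scores zero;
* *place-item matching*: one point per correctly reached furniture.

## Basic trajectory features

Total distance is the polyline length of the raw samples; duration is last
minus first timestamp; mean speed is **total distance over total duration**
(not the mean of instantaneous speeds) — with pauses included in the
denominator, a slow mean speed can reflect hesitation rather than slow gait,
which is exactly the clinical signal.

## Outlier mining

The walk is modeled as a 2-D constant-velocity state space, the standard
minimal model for pedestrian tracking: state (x, vx, y, vy), transition with
per-step `dt` from the actual timestamps, white-acceleration process noise of
spectral density `q` (discretized to the usual `[[dt³/3, dt²/2], [dt²/2, dt]]`
block), isotropic measurement noise `r`, initial state at the first sample
with zero velocity and covariance `init_cov_scale · I` (default 100).

Sample *k* (k ≥ 1) is an outlier when its innovation against the one-step-ahead
predictive distribution exceeds the chi-square(2) quantile at `gate_level`
(default 0.95, threshold 5.991). The gate is causal (filtered), matching the
sequential character of the data; a switch to smoothed-residual gating
(RTS smoother) exists but is off by default. Flagged samples still update the
filter — outliers are annotated, not excluded. Because both axes share the
same noise configuration the filter decouples into two 2-state filters with a
common scalar covariance recursion; tests verify exact agreement with an
independent full-matrix textbook recursion and with explicit 95%-ellipse
membership, and that the long-run flag rate on data simulated from the exact
model is the nominal 5%.

Maximal stretches of consecutive flagged samples form outlier runs; the
"distance of outliers" summary is the mean polyline length over each run's
raw observations (0 with no runs). Defaults `q = 0.8 (m/s²)²`, `r = 10⁻⁴ m²`
give a gate radius of ≈ 0.064 m at 13 Hz — wide enough that noise-free route
geometry (bounded-rate turns at waypoints) never trips the gate, narrow
enough that erratic wandering does. On synthetic control-group walks the
flag rate is ~1%.

## Stay-point detection

Anchor-scan formulation: from anchor `i`, advance `j` while
`dist(p_i, p_j) ≤ 0.3 m`; at the first excursion (or the trailing end) emit a
stay point iff `t[j−1] − t[i] ≥ 2 s`, with centroid the member mean and
(arrival, departure) = (t[i], t[j−1]); the anchor then jumps to `j` (emitted —
so stay points never overlap) or advances by one sample. The dwell condition
is inclusive (≥). The distance criterion is anchor-based, not pairwise
diameter. A brute-force O(n²) window oracle replays the same contract from a
full pairwise-distance matrix and must agree exactly on randomized inputs.

## Group statistics

For each feature: Lilliefors (Kolmogorov–Smirnov with estimated mean/SD)
normality per group via the statsmodels table approximation (for n < 4, below
the table's range, the null is simulated parametrically with 2,000
replicates), and Levene's test (center = mean) for variance homogeneity. If
every group is normal and variances are homogeneous: one-way ANOVA with
Bonferroni-adjusted pairwise pooled-variance t tests; otherwise:
Kruskal–Wallis (tie-corrected) with Dunn's pairwise z tests
(average-rank ties, Bonferroni over the three pairs). Adjusted p values are
capped at 0.999, mirroring the reporting convention of clinical statistics
software. Groups that are constant or too small for the normality test fail
the normality assumption and force the nonparametric branch; an
all-constant feature returns omnibus p = 1 with capped pairwise values
rather than erroring, so a pipeline run never dies on a degenerate feature.

Across the trajectory-mining family (outlier count, mean outlier-run
distance, stay-point count) the nine pairwise raw p values are jointly
Benjamini–Hochberg FDR-adjusted; the family is a configuration input because
reasonable analysts could group the comparisons differently. Pearson
chi-square (no continuity correction) handles categorical tables, with the
three 2 × 2 sub-tables Bonferroni-adjusted for three-group designs; Pearson
correlations use pairwise deletion and require n ≥ 3 and non-constant
variables. α = 0.05, two-sided, throughout. Under an exchangeable null the
full branch-then-test pipeline keeps the per-pair type-I error well under 7%
(the Bonferroni step makes it conservative; the pre-testing branch costs a
little level but not that much).

## Synthetic cohort generator

**What it emulates.** A waypoint-seeking walker per participant: for each
item, walk to the hiding section's centroid and back to the center, at
`base_speed` with per-step Gaussian heading noise, bounded turn rate
(15 rad/s), and three phenotype-dependent disturbances — wrong-target
excursions (probability per item), detour loops (probability per leg, extra
waypoint ~`detour_length/2` off the leg, walked hurriedly and erratically:
heading noise ×2, speed ×1.4), and pauses (Poisson in walking time,
exponential duration, position frozen exactly, speed ramped over 4 samples).
Samples are reflected at the arena boundary, so containment is exact.
Pauses longer than ~1.5–2 s become stay points; heading-noise tails and
detour bursts drive the innovation gate, so the noisier phenotypes accrue
more outliers and longer runs. Determinism: every draw flows from the
explicit integer seed (numpy `default_rng`); cohort participant *i* uses
trajectory seed `base + i` and response seed `base + i + 2²⁴`, so extending
a cohort never reshuffles earlier participants.

**Calibration.** The per-group knobs were calibrated by iterative simulation
(100 trajectories per group, seeds 0–99) so that cohort means reproduce the
published group structure: NC duration 246.7 s, NC stay points 13.7, AD stay
points 30.6, aMCI mean speed 0.19 m/s, and the orderings duration and stay
points NC < aMCI < AD, speed highest in aMCI, outlier burden AD > NC. Two
published values are deliberately not matched:

* the published distances (e.g. NC 57.9 m over 246.7 s) are inconsistent with
  the published NC mean speed of 0.16 m/s under speed = distance/duration;
  the generator resolves the conflict in favor of duration and speed, so
  synthetic distances are lower (NC ≈ 36 m) with the published distance
  ordering (aMCI > AD > NC) preserved;
* AD duration is set to ≈ 410 s (published 369 s) and aMCI stay points to
  ≈ 24 (published 26.4). With exponential pauses, the stay-point and
  pause-time targets pin the pause-duration mean, which in turn forces a
  duration SD of ≈ 70–90 s per group; at the published means the AD–aMCI
  gaps would then be too small for the three-way ordering to hold reliably
  in cohorts of 15 per group. Widening the two non-pinned gaps makes the
  ordering a property of the design rather than of luck.

Published per-participant outlier **counts** (~2,300–3,500, a large fraction
of all samples) are not reproducible from a 95% predictive gate and are not
calibration targets; only their group ordering is asserted.

**What it does not emulate.** No gait dynamics, fatigue, learning across
items, inter-item hiding-phase timing, head/controller streams, or tracker
dropout; response records are drawn independently per subtest with fixed
per-answer accuracies (no item-difficulty structure, no correlation between
walking and memory performance within participant). Passing tests therefore
show that the pipeline recovers group structure of this form — not that the
published effect sizes would replicate in new participants.

## Numerical and design notes

* Problem sizes in the shipped test suite: 100 trajectories per group for
  calibration recovery; 100 replicate 15/15/15 cohorts for
  direction-of-effect recovery; 10,000 exchangeable-null datasets (n = 10 per
  group) for the type-I error of the stats pipeline; 10⁵ model-matched
  samples for gate calibration; 200 randomized inputs for stay-point oracle
  equivalence.
* The generator caps a trajectory at one hour of samples as a termination
  guarantee; calibrated walks end after the ninth return leg (~4–6 min).
* Arrival at a waypoint uses a radius just above the bounded-turn circle
  (`1.1·v/ω`, floor 0.05 m; the boosted-speed detour legs use their own
  radius) so the walker can neither orbit a waypoint nor cut legs short by
  more than about one sample step.
* CSV output is deterministic: fixed column order, 6 decimal places; the
  pipeline manifest records seed, config hash and every file written.
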