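# Methods

This note documents the models, conventions and parameter choices behind
`fbindex`, in the spirit of a statistical package's model documentation:
what is computed, under which assumptions, which knobs matter, and what the
synthetic tests do and do not demonstrate.

## Coordinates and trajectory handling

Coordinates live in a tank-fixed frame with the origin at a bottom corner:
`x` along the 20 cm width, `y` along the 30 cm depth (the long horizontal
axis), `z` vertical.  All lengths are cm, time is seconds; minutes appear
only at the index layer.  Pixel input is calibrated through per-axis scale
factors declared in the file dialect.

Every sample carries a validity code (observed / interpolated / invalid).
`resample_and_fill` puts a recording on a uniform grid at the configured
rate (default 25 Hz — the tracking frame rate is an acquisition detail, and
all per-minute statistics are defined on time rather than sample counts, so
results are rate-robust).  Gaps up to `max_gap_s` (default 2 s) are filled
by linear interpolation and flagged; longer dropouts stay invalid and are
excluded from every denominator downstream.  Out-of-tank coordinates are
clamped to the walls with a count reported; clamping never alters validity.

**2D mode.**  With a single camera only two coordinates exist.  They are
interpreted as (horizontal, vertical): the second column is the vertical
axis, stored internally as `z`, because bottom-dwelling — the key welfare
signature — requires the vertical coordinate.  The package's own 2D writer
therefore names its columns `x_cm,z_cm`.  Depth-dependent quantities (the
`y` wall margin, the third occupancy-grid axis) degrade gracefully.

## The 20-characteristic ethogram

Per-interval kinematics use forward differences: step speed over valid
sample pairs, acceleration over valid triples, and the turn angle between
successive displacement vectors (computed in full 3D; in the plane in 2D
mode).  A step is assigned to the bottom or top half of the tank by the
vertical midpoint of its endpoints; an acceleration interval by its centre
sample.  Conventions for the characteristics without a published
definition, all configurable in `FeatureConfig`:

| convention | default | rationale |
|---|---|---|
| active-speed threshold | 0.5 cm/s | separates drift/tracking jitter from swimming at zebrafish scale |
| turn | heading change ≥ 45° | reuses the printed 45° angle of the fast-sharp characteristic |
| fast sharp move | speed > 12 cm/s and angle > 45° | printed definition; the outgoing step's speed is used |
| occupancy grid | 10×10×10 (10×10 in 2D) | fine enough to distinguish exploration styles, coarse enough to saturate for a healthy fish over 25 min |
| wall margin | within 10% of a lateral extent | floor/surface excluded, vertical preference is already `pct_time_bottom` |
| minimum segment | 60 s of valid step time | below this the vector is refused (`InsufficientDataError`), never silently zeroed |

Average deceleration is the mean magnitude of negative accelerations and
average acceleration the mean of positive ones; signed averaging would
conflate two separately listed characteristics.  A half with no valid
interval reports 0 for its restricted statistics plus an `empty-half` flag,
keeping grouped matrices rectangular.  Because paused fish produce
near-zero steps with random headings, the turn counter also counts
stationary jitter; this is the documented consequence of the literal
turn definition and is shared by the brute-force oracle.

## The index

The monitoring plane for the 3×3 zone grid is the side view (long
horizontal axis × vertical axis): the index must see bottom-dwelling, which
needs the vertical axis.  Cells are half-open with boundary points assigned
to the higher section.  A zone counts as visited if at least one valid
sample falls in it during the minute.  Per-minute Activity is thus
quantised in steps of 100/9 %.

The score combines Activity and Distance symmetrically: each contributes
`3·max(0, 1 − d/dev_max)` points, `d` the two-sided relative deviation from
baseline.  `dev_max = 1` means a metric's sub-score reaches zero at ±100%
deviation; the linear, truncated form reproduces the endpoints (6 = normal)
and makes hyper- and hypo-activity equally abnormal.  The printed category
table has gapped score bins (e.g. 2.1–4.0); scores are continuous, so bins
are implemented half-open and upper-edge inclusive, which reproduces the
printed normalised upper bounds 0.33 / 0.67 / 0.83 / 1.00 as `score/6`
rounded half-away-from-zero to two decimals.  (The printed *lower*
normalised bounds are inconsistent with `score/6` of the raw lower edges by
one rounding step; the upper bounds are reproduced exactly and the
discrepancy is left as printed.)

**Baselines.**  `A0_w`/`D0_w` are means over sliding windows (stride one
minute) of the pre-treatment recording.  Pre-treatment recordings are
25 min while the longest timescale is 30 min; the profile then uses the
largest feasible window and scales the distance reference proportionally,
with a warning.  A baseline with zero activity or distance is rejected —
a dead-still reference cannot anchor a relative score.

**Streaming.**  Windows not yet full are scored over the available minutes
and flagged partial; alerts (10-min timescale rated Unhealthy/Abnormal) are
suppressed until the window is full to avoid start-up artefacts.  Minutes
with less than 50% tracking coverage are excluded, the window's effective
length shrinking accordingly (the distance sum is rescaled to a full-window
equivalent); a window with under half its minutes covered yields "no
reading" rather than a score.  Multi-minute Activity is the mean of the
per-minute percentages (re-counting zones over the whole window would make
the metric saturate at 100% for any moderately active fish).

## The behaviour simulator

The simulator is a package construction — the simplest process that varies
the three result-bearing behaviours (speed, bottom time, exploration)
independently:

* a two-state active/paused Markov chain at 1 s granularity
  (`p_pause = 0.05`/s, `p_resume = 0.5`/s healthy: ~91% active, bouts of
  realistic length);
* while active, a correlated random walk in the horizontal plane — per-step
  speed from a truncated normal (healthy 6 ± 2 cm/s, matching vigorous
  zebrafish cruising), heading persistence 0.85 over 1 s;
* depth follows a damped second-order mean reversion toward
  `preferred_depth_frac × height` (healthy 0.55: mid-water).  A first-order
  position process cannot give cm-scale stationary spread and realistic
  instantaneous vertical speed simultaneously at 25 Hz, hence the
  velocity-damped form; `depth_attraction` (1/s) remains the position
  reversion rate, and `vertical_speed_sd` (healthy 1.5 cm/s) the stationary
  vertical speed scale;
* reflecting walls on all axes (billiard unfolding); while paused, position
  holds with sub-millimetre jitter.

The pain-like parameter set scales speed by 0.4, moves the preferred depth
to 0.15 of height with tighter holding, and triples the pause rate.  These
magnitudes are fixture conventions chosen to produce clear category
separation, not estimates of real effect sizes.  Scenario presets map the
observation windows (pre, 1, 2, 3, 6 h) to parameter sets: control/sham
time-invariant; fin clip fully affected from 1 h with no recovery; PIT tag
transient around 2 h; 1% acid mild and transient; 5%/10% acid affected
through 3 h and recovered by 6 h; a 10%-acid top-dwelling variant
(preferred depth 0.85); analgesic-rescued fin-clip variants healthy-like
throughout.  Cohort seeds derive deterministically from a master seed, so a
cohort is a pure function of its design and seed.

What the simulator does *not* emulate: tracking noise and identity swaps,
wall-hugging thigmotaxis as a distinct state, startle bursts, diurnal
drift, or any physiological model of nociception.  Passing tests on
synthetic cohorts therefore demonstrate the correctness and discriminative
mechanics of the pipeline under controlled behaviour shifts — not field
performance on real recordings.

## Evaluation

The grouping rule labels as *control* every control-group row plus every
pre-treatment row of the other groups, and as *pain* the 2, 3 and 6 h rows
of the invasive-treatment groups; sham post-treatment rows and 1 h rows
enter neither class.  PCA is an eigendecomposition of the column
correlation matrix (sample standard deviations, `ddof = 1`); explained
variance is reported pre-rotation, since rotation does not change it, and
the three-component report cut is a fixed parameter.  Component signs are
fixed by making each component's largest-magnitude loading positive.

KMO and Bartlett's sphericity follow their closed forms (anti-image partial
correlations from the inverse correlation matrix; `χ² = −(n−1−(2p+5)/6)
ln det R` on `p(p−1)/2` df).  The 20-characteristic matrix is exactly
rank-deficient by construction (`total_distance = distance_top +
distance_bottom`, and on gap-free tracking `avg_speed` is `total_distance`
over a constant time), so KMO falls back to the pseudo-inverse with a
warning and Bartlett refuses the singular matrix; reports therefore compute
the adequacy statistics on the remaining 18 linearly independent
characteristics.

On synthetic cohorts PC1 (≈84% of variance, loading on speed/distance)
separates control from pain rows with disjoint interquartile ranges; the
synthetic matrix is far cleaner than real tracking data, which is why its
PC1 share is much larger than would be expected from biological recordings.

## Problem sizes and numerics

The reproduction script and the cohort-level tests use the study-shaped
design (7 fish per group, 25-min recordings at 25 Hz, 37 500 samples per
recording) with 3–10 master seeds per statistic — enough for the stochastic
properties to be stable while keeping a full run in tens of seconds.
Floating-point conventions: streaming and batch evaluation sum window terms
in the same order (equal to the last bit); self-scoring a constant series
is exact up to accumulation error below 1e-9; oracle comparisons of the
ethogram use 1e-9 relative tolerance.  Degenerate inputs (empty files,
all-invalid minutes, dead-still baselines, zero-variance columns) raise
typed, named diagnostics rather than producing silent zeros.

## Known limitations

* The Activity/Distance → score combination (equal weights, linear
  truncation at `dev_max`) is this package's formalisation; only its
  endpoints and category bins are externally anchored.
* Feature thresholds without published definitions (activity, turns, wall
  margin, occupancy resolution) are package conventions, surfaced in one
  config object.
* Single-fish monitoring only; shoal scoring is out of scope.
* The simulator's realism limits (above) mean synthetic benchmarks
  quantify pipeline behaviour, not expected performance on real tanks.
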