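# Methods

This note documents the quantitative definitions the package
implements, the synthetic model used to verify them, and the numerical
and design choices that were genuinely open.

## Units and data model

Internal units are millimetres and seconds throughout; thresholds quoted
in the worm-tracking literature in mixed units are converted once at
configuration load (0.02 cm·s⁻¹ → 0.2 mm/s immobility cutoff; 500 µm/s →
0.5 mm/s tracker ceiling). Coordinates are plate-centric Cartesian with
the origin at the plate centre and the x-axis along the control↔odorant
axis; no image-pixel conventions enter the data model.

A track is one animal's ordered series of centroid and head-tip
positions with strictly increasing times. Tracking gaps are represented
in-band (`valid=False` frames) rather than by splitting tracks, because
per-animal measures aggregate over one logical trajectory. Column
mappings for tracker exports are configuration-driven; a WormLab-like
reference dialect ships as the default. Frame rate is not assumed: the
dialect carries the frame interval explicitly, and the synthetic default
is dt = 0.1 s (10 fps, typical for plate-scale tracking, making the 3-s
detection window 30 frames).

## Chemotaxis scoring

CI = (B − A)/(A + B) per plate, with the central 1-cm band (half-width
5 mm on a 50-mm plate) excluded from the index but reported. A plate
with A + B = 0 is flagged unscorable and excluded from statistics with a
logged reason rather than scored 0. The per-plate CI — not the pooled
count — is the statistical unit, matching boxplots of plate values;
pooled-count CI is a secondary output. Zone assignment from tracked
positions uses the signed distance to the midline and reports
odorant-anchored counts, so left/right alternation across trials
cancels by construction. Endpoint counts are treated as final (the
anesthetic at the scoring spots fixes arriving worms); no time-resolved
scoring is computed. Assay durations (60 min adults, 120 min L3) are
metadata only.

## Kinematics

- **Instantaneous speed**: per-step centroid displacement divided by the
  actual inter-frame interval; a step is valid only if both endpoint
  frames are valid.
- **Immobility** is a step property; steps with speed < 0.2 mm/s are
  excluded before the per-animal median (strict `<`, so exactly
  0.2 mm/s survives). If no step survives, the animal is reported as
  immobile (NaN median), which is distinct from a 0 median.
- **Outlier rule**: the 0.5 mm/s ceiling applies to the per-animal
  median ("up to" 0.5 is trackable, so exactly 0.5 is kept; strictly
  greater is excluded and logged). It removes individuals, not frames.
- **Track length** sums step distances over valid steps only. Gap steps
  are excised, never interpolated: interpolation would fabricate path
  length and bias the head-swinging index downward.
- **Head-swinging index** = head track length / centroid track length,
  with the identical step-validity mask in numerator and denominator. A
  zero centroid length makes the index undefined; the animal is flagged,
  not silently dropped. An optional moving-average position smoother
  exists (default off, use logged) because positional jitter inflates
  both path lengths.

## Pirouette detection

Headings are taken from centroid displacement spans via atan2, wrapped
to (−180°, 180°]; successive wrapped differences are the turn
increments. Two guards keep noise out of the turning signal:

1. a **minimum-displacement floor** (0.01 mm): spans shorter than this
   have numerically meaningless headings and are masked;
2. a **resampled heading timebase** (default 0.5 s; configurable, set
   0/None for per-frame): at 10 fps, per-frame displacements of a
   0.2–0.4 mm/s worm are 0.02–0.04 mm, comparable to realistic
   positional jitter, so per-frame headings are noise-dominated and the
   displacement floor alone cannot mask them. Displacement over ~0.5 s
   is dominated by true motion while reorientations on the 3-s scale of
   the detection window are fully preserved; this also matches the
   ~1–2 Hz turning-rate sampling of the classical pirouette literature.
   Whether commercial trackers compute their cumulative turning angle
   per-frame or resampled is unstated and proprietary, so the timebase
   is exposed in configuration and reported with results.

The detector scans every sub-interval of contiguous defined-heading
spans with duration ≤ 3 s. A candidate fires when |net signed sum of
increments| > 120° **and** mean speed over the same sub-interval is at
most 60% of the mean speed over the 2 s preceding it (the baseline is
anchored at the window start; candidates whose baseline has under half
its spans valid, or that start before one full baseline has elapsed, are
skipped and logged). "Cumulative turning" is read as the **net** signed
sum by default: a sum of absolute increments would fire on vigorous
body/head oscillation without any actual reorientation — precisely the
behavior of a strongly head-swinging, rarely-pirouetting worm — which
would make the two measures confound each other. The absolute mode is
available as a configuration switch and the mode used is reported.

Overlapping or abutting candidates, and candidates separated by < 1 s,
describe one behavioral event and are merged; the merged event carries
the bounds and statistics of its maximal-|net turn| candidate (|net
turn| compared after rounding to 1e-6° so the winner is stable under
rigid-motion float noise, ties broken to the earliest candidate).
Detection uses the centroid only; head oscillation never enters the
turning signal. Rates are events per minute of **valid** observation
time. The windowed implementation is exactly equivalent to an
exhaustive O(n²) sub-interval scan (verified against an independent
brute-force oracle with event-set equality after merging).

## Synthetic worms and plates

The generator provides ground truth for recovery tests; it emulates the
statistical structure the analysis assumes, not worm biomechanics.

- **Centroid**: correlated random walk. Heading integrates Gaussian
  turning noise of variance `heading_diffusion·dt` (deg²/s); speed is a
  stationary lognormal AR(1) with mean `mean_speed` and coefficient of
  variation `speed_cv`.
- **Pirouettes**: injected as signed net turns (magnitude Gaussian
  around `pirouette_turn` with 10% sd, truncated at 130° so recovery
  tests never straddle the 120° threshold) spread over
  `pirouette_duration` while speed is multiplied by
  `pirouette_speed_factor`. Event starts follow a hard-core renewal
  process — minimum gap = event duration + 4 s, exponential excess with
  mean chosen so the long-run rate equals `pirouette_rate` exactly —
  which prevents overlapping injections and double-merge ambiguity
  without biasing the injected rate. Events stay clear of the first 3 s
  and last ~3 s of the track so a full baseline and window always exist.
- **Head tip**: centroid + `head_offset` along the heading + a lateral
  sinusoid of amplitude `head_amp` and frequency `head_freq`.
- **Degradation**: iid Gaussian positional jitter (`noise_sd`) on
  centroid and head independently; iid frame dropout (`gap_prob`).
- **Plates**: endpoint counts are one multinomial draw per plate over
  (control, odorant, central) probabilities with 10 worms by default.

Determinism: one root seed; ensembles derive per-track streams by
counter offset, so results are independent of generation order.
Ground-truth metadata rides on the track object and is never read by
analysis code.

Two presets encode the qualitative species contrasts: *elegans-like*
(0.38 mm/s, head amplitude 0.08 mm at 0.5 Hz, 0.5 pirouettes/min) and
*inopinata-like* (0.24 mm/s, 0.30 mm at 0.8 Hz, 0.02 pirouettes/min).
No published per-animal numbers exist in text form for these species'
speeds or head amplitudes, so the preset values are the package's own
choices, placed inside the trackable band (0.2, 0.5] mm/s implied by the
immobility and tracker-ceiling thresholds; only ordinal relations
between the presets are asserted anywhere.

What the generator does **not** emulate — and hence what passing
recovery tests do not show about real data: odorant-gradient navigation
(synthetic worms are condition-agnostic random walkers; there is no
klinotaxis steering), body posture and undulation (the head is a
kinematic decoration, not a neck), reversals as distinct from omega
turns, tracker segmentation artifacts (collisions, identity swaps,
coiling), and spatially structured dropout (gaps are iid, real gaps
cluster).

## Statistics

- **Wilcoxon rank-sum**, two-sided. Exact permutation p when
  n₁+n₂ ≤ 12 with no ties; otherwise the normal approximation with tie
  and continuity corrections. Ties always force the corrected
  approximation. Identical constant samples return p = 1 with a
  degenerate-data warning. The exact path is verified against full
  rank-assignment enumeration for every configuration up to n₁+n₂ = 10.
- **Effect sizes**: median differences with percentile-bootstrap 95%
  CIs (10,000 resamples by default; seed mandatory so outputs are
  replayable). Percentile rather than BCa is the minimal reading of
  "bootstrap resampling"; note percentile intervals need not cover the
  point estimate under heavy skew, so only ci_low ≤ ci_high is
  guaranteed.
- **Kruskal–Wallis** with tie correction; a pooled constant sample
  yields H = 0, p = 1 (the tie-corrected statistic is otherwise 0/0).
- **Dunn's post-hoc** z-tests on pooled mean ranks with the standard
  tie term, two-sided normal p, and **Benjamini–Hochberg** step-up
  adjustment. The BH family is all pairwise comparisons within one
  Kruskal–Wallis analysis, not across measures or odorants. BH is
  order-preserving; it is *not* idempotent in general (re-adjusting an
  adjusted vector can inflate it further), so no idempotence is claimed.
- Significance is flagged at α = 0.05 on the adjusted p where present.

## Problem sizes used in verification

The test suite and acceptance script size their simulations to keep the
whole run in the tens of seconds while leaving Monte-Carlo error well
inside each tolerance: 1,000 plates for CI-estimator consistency
(checked within 3 MC standard errors of the enumerated multinomial
expectation), 200 plates for the null-control median, 20 × 30-min tracks
for pirouette-rate recovery (±10%), 50 random tracks ≤ 2,000 frames for
detector/oracle equality, 5,000 null replicates for Wilcoxon type-I
calibration, and 500 replicate studies (n = 30/30, 2,000 resamples) for
bootstrap-coverage checks.

## Known limitations

- The pirouette detector reports one event class; reversal vs
  omega-turn decomposition is out of scope.
- Multi-worm identity re-linking across gaps is out of scope; a track
  is trusted as one animal.
- The CI treats half-plates as scoring areas; if worms were instead
  counted only at the anesthetic spots, absolute CIs would differ
  (half-plate counting is implemented as the declared rule).
- Bootstrap CIs for medians at small n inherit the discreteness of the
  sample median; coverage is calibrated (92–98% in simulation) but not
  exact.
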