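# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `deepdive`.  It is the package's own account of its
science; every number quoted here is computed by the test suite or the
acceptance script, not asserted from memory.

## Frames and conventions

Depth is metres positive down; track coordinates are x = east, y = north.
Angles are radians internally and degrees in CSV outputs.  Pitch is
positive nose-up in [−π/2, π/2] (descent negative), roll and heading wrap
to (−π, π], heading 0 = north, clockwise positive.  The whale-frame
accelerometer reads `(0, 0, g)` for a level animal and `(−g, 0, 0)` in a
vertical nose-down descent, which fixes `pitch = asin(a_x/|a|)` and
`roll = atan2(a_y, a_z)`.  Heading comes from the magnetic vector after
de-rotating by the estimated roll then pitch (tilt compensation).
Magnetic declination is deliberately omitted: every downstream use of
heading is a variance, a difference or a closed-loop displacement, in
which a constant offset cancels.

Sample conventions: a sample on a phase boundary belongs to the later
phase (half-open intervals); surface-crossing times are linearly
interpolated between samples.

## Orientation estimation

Posture is separated from propulsion by a zero-phase moving average
(default 3 s) on accelerometer and magnetometer before the angle
formulas.  The window is a trade-off: long windows suppress propulsion
and prey-capture transients but attenuate genuine fast orientation
change.  On noise-free synthetic streams a 0.5-s window recovers the
generating pitch/roll/heading to < 1° RMS (acceptance suite).  Samples
whose filtered acceleration norm stays below 0.5 g are flagged
(`low_gravity`) and a quality warning is emitted when the condition
persists for more than a second — in practice this marks active bottom
phases where dynamic acceleration genuinely dominates, and it is a
signal to treat orientation-derived statistics there with care.

## Dive detection and phase segmentation

A dive spans from the last upward crossing of the 5-m near-surface band
before the 40-m threshold is exceeded to the next return into the band.
The threshold defines what counts as a dive; the 5-m band makes the
*duration* well defined, since the criterion itself says nothing about
where a dive begins.  Submergences shorter than 60 s are discarded as
pressure spikes; excursions cut by a record edge or sensor gap are kept
but flagged incomplete and excluded from metrics.  Missing CSV rows
split a record into segments and no dive is ever detected across a gap
(the alternative — bridging gaps — fabricates phase boundaries).

Phases follow the pitch-sign definition: descent ends when pitch
(smoothed over 5 s; exact zero tests on raw noisy pitch are unstable)
first exceeds 0°, ascent starts where pitch is last below 0°.  If the
first crossing falls after the last one the dive is V-shaped: the bottom
phase is empty and both boundaries collapse onto the single zero
crossing.  Bottom-phase statistics of V-dives are reported missing
(NaN), never zero.

Descent rate is depth gained between dive start and descent end over
that interval; ascent analogous (absolute value).  Circular variances
(1 − mean resultant length; 0 = no dispersion, 1 = uniform) and the jerk
coefficient of variation (SD/mean of |Δa|·fs, n−1 denominator — scale-free,
hence robust to the 32 vs 50 Hz tag difference in *amplitude* terms,
though not exactly rate-invariant) are computed over bottom-phase samples
only.

## Dive typing

K-means (Euclidean, 50 seeded restarts per K, empty clusters re-seeded
from the farthest points) on the raw feature vector (duration s, max
depth m, ascent and descent rate m s⁻¹).  The features are deliberately
*not* scaled — this preserves comparability with the original analyses
and means the distance relies far more on depth and duration than on the
rates; the suite asserts this non-invariance rather than hiding it.  The
silhouette coefficient picks K over candidates 2–6 (ties to the smaller
K); `subsample_robustness` refits on repeated without-replacement
deployment subsamples (default 6 deployments × 30 reps) to check the
chosen K is not a sample-size artefact.  Cluster names are assigned by
centroid depth order (short_shallow < mid_depth < long_deep).

## Foraging classification and budgets

Bottom-phase roll variance is the acoustic-free foraging indicator.  The
cutoff is calibrated against click-bout labels by minimising the count of
disagreements (clicking-but-classified-non-foraging plus
silent-but-classified-foraging, weighted equally — the published analysis
reports both counts symmetrically).  The objective is piecewise constant,
so candidates are the midpoints between consecutive sorted unique roll
variances; the interval endpoints 0 and 1 are added so the degenerate
optima ("everything"/"nothing" foraging) remain representable — without
them a dense grid scan can beat the candidate set.  Ties resolve to the
smallest threshold.  Classification is strict (`roll_var > threshold`);
dives without bottom metrics are non-foraging.  Tags without acoustic
coverage (click annotation `None`, as for the no-audio location) are
excluded from calibration but classified like any other dive.

Time budgets are percentages of the analysed (post-trim) record: surface
(complement of all dive spans — so surface + dives ≡ 100 by
construction), foraging dives, and bottom phases of foraging dives.
Diving efficiency per foraging dive is bottom duration over (dive
duration + post-dive time to the next foraging dive); the last foraging
dive of a deployment has no observed post-dive time and is dropped.

## 3-D movement

Dead reckoning integrates `speed · cos(pitch) · dt` along the heading
(forward Euler) from the dive-start origin, with depth taken from the
pressure sensor; measured paddlewheel speed is used when present and a
constant 2 m s⁻¹ otherwise.  Additive drift with time is inherent and
acknowledged — tracks are pseudo-tracks for within-dive structure, not
georeferenced positions.

The tortuosity index is implemented as `TI = 1 − net/total` horizontal
distance.  The prose definition circulating for this quantity ("the ratio
of net to total distance") contradicts its stated endpoints (0 straight,
1 circular); the implementation honours the endpoints, which is also what
the acceptance benchmark checks (closed circle → TI = 1, straight → 0,
semicircle → 1 − 2/π).  TI and roll variance are reported per 50-m depth
band separately for descent and ascent (bands with < 5 samples omitted),
plus one pooled stratum per between-dive surface interval.

Gyrations — continuous rotations of at least two full turns, roll during
descent and heading during ascent — are detected on the unwrapped angle
by a monotone-run scan that tolerates reversals below 45°.  Runs are
located on a 0.5-s-smoothed copy (so sensor noise cannot fake a 45°
reversal mid-rotation) while the cumulative rotation is read off the raw
angle at the run endpoints, keeping turn counts exact on clean data.
`n_rotations = floor(|Δ|/360°)`.  The ≥ 2-turn criterion is given; the
45° tolerance and the per-turn quantisation are this package's choices.

## Synthetic deployments

The generator is first-class, tested code: it defines the conditions the
analysis is validated under.

* **Dive plan.** Types are drawn from a mixture; per-dive maximum depth,
  duration and vertical rates are truncated normals (±4 SD and physical
  floors: 45 m depth so every dive crosses the 40-m criterion,
  0.15 m s⁻¹ rates, 2 min duration).  Defaults are the published
  per-location type statistics: Jan Mayen short-shallow 121.6 ± 61.9 m /
  8.2 ± 4.0 min, mid-depth 430.4 ± 189.6 m / 20.5 ± 3.9 min, long-deep
  888.8 ± 407.4 m / 41.1 ± 5.7 min (mixture 165:167:32); Gully
  short-shallow 171.6 ± 96.0 m / 13.9 ± 7.2 min, long-deep
  1188.0 ± 456.8 m / 43.6 ± 6.9 min (61:15); a named alternative scenario
  carries the summary-level foraging depths (967 ± 394, 1247 ± 411,
  537 ± 135 m).  When a drawn combination cannot fit descent + ascent
  transit plus a 90-s minimal bottom phase, depth is capped to what the
  drawn duration allows (duration extended only if even the floor does
  not fit) — capping depth keeps all four marginals inside their stated
  ranges, whereas extending duration produced multi-hour outliers when a
  deep dive drew a near-floor rate.
* **Within-dive structure.** Depth is piecewise linear (descent at the
  drawn rate, gently undulating bottom, linear ascent), so measured rates
  equal the drawn ones.  Pitch is steeply negative in descent
  (−60…−30°, drawn per dive), crosses zero *exactly* at the
  descent/bottom and bottom/ascent boundaries through ±8-s linear ramps
  (so 5-s smoothing does not move the crossing), and is positive in
  ascent — giving the pitch segmentation an exact ground truth.
* **Angles.** Roll and heading are smooth cubic-spline processes over
  Gaussian knots.  Bottom-phase dispersion is *calibrated*: the process
  is scaled by a root search until its empirical circular variance equals
  the target (active 0.6 / quiet 0.15 for roll; 0.5 / 0.1 for heading),
  making the generator's variance contract exact rather than asymptotic.
  Foraging (active) bottoms occur with the per-type probabilities
  implied by the published foraging composition (25/165, 105/167, 26/32;
  18/61, 14/15).  Surface headings follow a smooth random walk (±40° per
  5-s knot), giving the high near-surface tortuosity seen in real tracks.
* **Sensors.** Acceleration is gravity rotated by (pitch, roll) — via
  explicit rotation matrices, an independent code path from the
  closed-form estimator — plus optional white noise and, in active
  bottoms, sparse half-sine prey-capture transients (0.15 s⁻¹ Poisson
  rate, 2–6 m s⁻², kept ≥ 3 s clear of phase boundaries so boundary
  detection is tested against behaviour, not artefacts; `jerk_transients=False`
  disables them for gravity-only round-trip tests).  Magnetism is the
  earth field (inclination default 75°, high-latitude-like) rotated into
  the sensor frame.  Gravity is 9.81 m s⁻².
* **Gyrations** are injected as additive monotone ramps of whole turns
  (40°/s), which keeps the wrapped series continuous at both ends and
  the event count unambiguous.
* **Layout.**  Surface intervals are log-normal (median 480 s, σ = 0.5 —
  no distribution is published; this keeps plausible 5–15 min recovery
  times), with a configurable lead-in before the first dive (the study
  pipeline uses 22 min so the standard 20-min trim leaves all dives).
  Click bouts span active bottom phases (2-s margins).
* **Randomness** is split into three child streams (plan / angle
  processes / sensor noise) so the dive plan — and with it dive-level
  ground truth — is identical across sampling rates; this is what makes
  the "budgets invariant to fs" property testable against a common truth.
* **Isotopes** are independent bivariate normal draws per
  location × year group; defaults reproduce the published group sizes,
  means and SDs (e.g. Jan Mayen 2014: n = 12, δ15N +14.96 ± 0.36,
  δ13C −18.55 ± 0.18), with diagonal covariance (no within-group
  correlation is published).

What the generator does *not* emulate: correlated depth/duration
structure within a type (only marginals are published — see
limitations), hydrodynamics and speed variation, acoustic waveforms,
tides/currents, tag slippage, and diel effects.  Passing tests therefore
demonstrate that the pipeline recovers what this generative model plants
at field-realistic scales, not that it would be unbiased on any real
deployment.

## Isotopic niches

SEA = π√(λ₁λ₂) from the eigenvalues of the 2 × 2 sample covariance (the
standard ellipse, ≈ 40% coverage of a bivariate normal — the "core"
niche); SEAc multiplies by (n−1)/(n−2).  The core niche is reported via
the ellipse, not a 40% hull: the two phrasings in circulation conflict,
and the ellipse is the definition under which the published per-year
values are stated.  TA is the convex-hull (shoelace) area of all points;
collinear groups get TA = 0 with a warning.  Ecoregion baseline offsets
are differences of zooplankton means (Jan Mayen −23.61/+6.47 vs Scotian
Shelf −21.89/+5.28 ‰ → +1.72/−1.19, reported rounded to +1.7/−1.2) added
to one group's values before cross-region comparison.  Secular δ13C
depletion (Suess/Laws) is consumed as user-supplied per-year offsets
(default zero) rather than re-deriving a regional correction model.
Group comparisons use Welch's t-test by default (no equal-variance claim
is published); an optional flag excludes the anomalous 2015 Scotian
Shelf sample (−14.76, +17.53) rather than dropping it silently.
Mixed-model and beta-regression comparisons of budgets and foraging
characteristics are out of scope: the pipeline exports tidy tables for
off-the-shelf statistical tools.

## Numerical choices

* Sample SD uses the n−1 denominator throughout.
* Circular variance is clipped to [0, 1]; TI to [0, 1].
* Jerk CV with zero mean raises (undefined, not 0); TI of a stationary
  or purely vertical segment raises and the band is skipped.
* K-means ties across K resolve to the smaller K; threshold-calibration
  ties to the smallest candidate; singleton clusters get silhouette 0.
* Boundary samples belong to the later phase; crossings are
  interpolated linearly.
* Reported percentages are rounded to 1 decimal in output tables
  (configurable), matching conventional reporting style.

## Problem sizes

The default study runs 15 Jan Mayen deployments (24 dives each, with
clicks) and 6 Gully deployments (13 dives, no audio) at 32 Hz —
≈ 360 + 78 dives, the scale of the original dataset — in roughly a
minute on one CPU.  Unit tests use miniature dive types (3–12 min dives
at 16 Hz) for speed; full-scale parameters are exercised in the
acceptance suite.

## Known limitations

* The published per-type statistics are *marginal* means/SDs.  Drawn
  independently, adjacent types overlap more than real dives do (real
  depth and duration co-vary within a type): with the published Jan
  Mayen parameters the short-shallow and mid-depth duration
  distributions cross near their 95th/5th percentiles, so
  label-recovery of a K-means fit saturates around ARI ≈ 0.77 and the
  silhouette prefers K = 2 on such draws.  This is a property of the
  summary statistics, not of the clustering code — the corresponding
  acceptance test documents it by failing honestly, and clustering
  recovery is demonstrated on separable synthetic types instead.
* Dead-reckoned tracks drift without surfacing fixes; no GPS fusion.
* The orientation estimator assumes the mounting rotation is already
  applied and gravity dominates the filtered signal; it degrades in
  high-dynamics bottom phases (flagged, not corrected).
* Click bouts are consumed as annotations; no audio processing.
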