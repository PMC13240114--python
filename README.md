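# deepdive

Dive-behaviour and isotopic-niche analysis for multi-sensor whale
biologging tags, built around the workflow used to compare northern
bottlenose whale (*Hyperoodon ampullatus*) populations between deep-water
canyon habitats: orientation estimation from accelerometer/magnetometer
streams, pitch-based dive-phase segmentation, K-means dive typing with
silhouette model selection, roll-variance foraging classification
calibrated against echolocation click bouts, deployment time budgets,
dead-reckoned 3-D pseudo-tracks with depth-band tortuosity and gyration
detection, and bivariate skin-isotope niche metrics.

It is written for movement ecologists who have depth + triaxial
acceleration + triaxial magnetism records (32–50 Hz tag data in CSV form)
and/or skin-biopsy δ13C/δ15N tables, and want a tested, scriptable
re-implementation of this analysis chain — plus a synthetic-deployment
generator with full ground truth, so every stage can be validated without
field data.

## The analysis in brief

* **Orientation.** Pitch/roll come from the low-pass-filtered gravity
  component of whale-frame acceleration (`pitch = asin(a_x/|a|)`,
  `roll = atan2(a_y, a_z)`); heading from tilt-compensated magnetism.
  A level whale reads `(0, 0, g)`; a vertical nose-down descent reads
  `(-g, 0, 0)` (pitch −90°, descent negative).
* **Dives and phases.** A submergence deeper than 40 m is a dive. The
  bottom phase runs from the end of descent (smoothed pitch first exceeds
  0°) to the start of ascent (pitch last below 0°).
* **Dive types.** K-means on the *unscaled* feature vector
  (duration s, max depth m, ascent rate, descent rate); the silhouette
  coefficient SC (mean of `s(i) = (b−a)/max(a,b)`) selects K.
* **Foraging.** A dive is foraging iff its bottom-phase roll circular
  variance (`1 − R̄`, the mean resultant length) strictly exceeds a
  threshold calibrated by minimising disagreement with click-bout labels.
* **Movement.** Pseudo-tracks are dead-reckoned at 2 m s⁻¹ (or measured
  paddlewheel speed); tortuosity index `TI = 1 − net/total` horizontal
  distance per 50-m depth band (0 = straight, 1 = closed loop); gyrations
  are ≥ 2 continuous full rotations (roll in descent, heading in ascent).
* **Isotopes.** Per-group standard ellipse area `SEA = π√(λ₁λ₂)` from the
  sample covariance, small-sample corrected `SEAc = SEA·(n−1)/(n−2)`,
  convex-hull total area TA, ecoregion baseline offsets from zooplankton
  means, and Welch t-tests between locations.

## Worked example

```python
import deepdive as dd
from deepdive import synthetic_data as sd

series, truth = sd.simulate_deployment(
    sd.JAN_MAYEN_SPECS, sd.JAN_MAYEN_MIXTURE, n_dives=6, fs=32.0, seed=7,
    deployment_id="jm_demo", location="JanMayen")

ori = dd.estimate_orientation(series)
jerk = dd.compute_jerk(series)
dives = dd.detect_dives(series, threshold_m=40.0)
metrics = []
for d in dives:
    dd.segment_phases(d, ori)
    metrics.append(dd.dive_metrics(d, series, ori, jerk))

model = dd.calibrate_threshold([m.roll_var_bottom for m in metrics],
                               [m.has_clicks for m in metrics])
labels = dd.classify_foraging(metrics, model.threshold)
budget = dd.time_budget(series, dives, labels)
```

prints (via the obvious `print` statements):

```
6 dives detected in 2.5 h
  dive 0:   195.7 m   22.6 min  roll_var=0.56  clicks=True
  dive 1:   135.9 m   12.4 min  roll_var=0.13  clicks=False
  dive 2:   473.2 m   21.5 min  roll_var=0.56  clicks=True
  dive 3:   534.1 m   17.6 min  roll_var=0.54  clicks=True
  dive 4:   227.9 m   16.0 min  roll_var=0.13  clicks=False
  dive 5:   218.3 m   12.6 min  roll_var=0.13  clicks=False
threshold=0.339  mismatches=0
surface 32.0%  foraging 40.9%  bottom-of-foraging 15.8%
```

Dives with active (high roll variance) bottom phases coincide with the
click bouts, so the calibrated threshold (0.339) separates them with zero
mismatches; the time budget splits the record into surface time, time in
foraging dives and time in their bottom phases.  The isotope side works
the same way from a tidy samples frame:

```python
iso = sd.simulate_isotopes(seed=7)          # 18 + 41 samples, two regions
nm  = dd.niche_metrics(iso[iso.location == "JanMayen"], "JanMayen")
off = dd.baseline_offsets(sd.ZOOPLANKTON_BASELINES["JanMayen"],
                          sd.ZOOPLANKTON_BASELINES["ScotianShelf"])
# nm.seac -> 0.16 permil^2, nm.ta -> 0.44 permil^2, off.rounded() -> (1.7, -1.2)
```

The command line mirrors the library
(`deepdive simulate|segment|type|classify|budgets|track|isotopes|pipeline`,
each with `--config/--seed/--out`); `deepdive pipeline --seed 1 --out out/`
runs the full two-location synthetic study and writes all result tables
plus a JSON manifest recording config, seed, versions and input digests.

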