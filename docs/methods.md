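# Methods

This note documents the models, parameter choices and numerical
conventions behind `onhcmap`, and what the synthetic data can and cannot
establish about real recordings.

## Coordinate frame and stimulus geometry

All maps live in a single right-eye visual-field frame (x positive
temporal, y positive superior, degrees of visual angle); left-eye data
are mirrored in x before analysis, so cohorts can be pooled.

The 61-element stimulus array has rings of 1, 6, 12, 18 and 24 hexagons.
Element size must grow with eccentricity (to elicit responses of
comparable size across the field), but published descriptions fix only
the element count, the scaling intent, and the ~30° outer radius, so the
construction is ours: a uniform hexagonal tessellation is built in axial
coordinates, its shared vertex set is pushed through a strictly monotone
piecewise-linear radial map whose segment slopes are the per-ring scale
factors (default 1.0, 1.25, 1.55, 1.90, 2.30), and the result is scaled
so the outermost vertex sits at exactly 30°.  Because adjacent elements
share the very same mapped vertices, the scaled array still tiles the
field exactly — the test suite verifies zero pairwise polygon overlap
and raster-union area equal to the summed polygon areas.

The 30-2 grid is the standard 76-point pattern on the 6° lattice offset
3° from both meridians; the two points at (+15°, ±3°) flank the
physiologic blind spot and are excluded from all masks.  The optic disc
defaults to (15.5°, −1.5°) in field coordinates (configurable).

Fibre-path distance from a field location to the disc supports two
models: `euclidean` (straight line × 0.30 mm/deg, both configurable) and
`bundle`, the shortest path that does not cross the horizontal raphe
temporal to the disc (modelled as the ray y = raphe_y, x ≥ disc_x; a
blocked path detours via the ray origin and is therefore never shorter
than the euclidean one).  The simulator's conduction-delay model uses
the euclidean distance by default.

## ONHC amplitude extraction

The amplitude rule is: smooth the trace, take the signal level at 20 ms
as baseline, enumerate the local maxima of the 60–90 ms epoch in time
order, keep those above baseline, and report (second peak − baseline) —
falling back to the sole peak when only one exists and to 0 when none
does, clamped at zero.  Two numerical guards make this rule usable on
noisy traces:

- **Smoothing** is a Savitzky–Golay filter, window 9 samples (~7.5 ms at
  the default 0.83 ms sampling), order 2.  A quadratic kernel preserves
  peak heights far better than a plain moving average: on a planted
  10 nV/deg² deflection with 0.5 nV/deg² white noise (200 repeats) it
  recovers 9.77 ± 0.98, where a 3-sample moving average gives
  9.13 ± 2.32.  Order 0 degenerates to a moving average; window 1
  disables smoothing.
- **Minimum prominence** (default 0.5 nV/deg², about one noise SD):
  a local maximum only counts as a peak if its topographic prominence
  within the epoch reaches this value.  Without it, residual noise
  wiggles in the valley between the first IC deflection and the ONHC are
  counted as the "second maximum", which collapses the measured
  amplitude on ~5% of healthy hexagons.  Setting it to 0 restores the
  raw enumeration rule.

Peak heights are read from the smoothed samples directly (no sub-sample
interpolation), which bounds the noise-free error at ≤1% of the peak for
the default deflection width; the implicit time, where requested, is
refined to sub-sample precision with a three-point parabola, which is
what makes the nasotemporal latency gradient resolvable between hexagons
whose conduction delays differ by less than one sample.

Baseline is the single interpolated sample at 20 ms by default; an
optional ±2 ms averaging window is available.  The epoch (60–90 ms) and
baseline time are configurable.

## Normalisation, staging, cut-offs

The reference `Ā₇` is the mean of the seven largest amplitudes among
elements of rings ≤ 3 (configurable to the whole array), ties broken
toward the lower element id for determinism.  In healthy eyes the seven
winners are essentially the central seven elements (rings 1–2), which
cover the central ~10° that glaucoma tends to spare — the rationale for
an intra-individual reference.  Ratios are reported at nine decimal
places, making them exactly invariant to any overall recording gain.
Stage boundaries use strict `<` at 0.5/0.3/0.2/0.1, so the four masks
are nested by construction.

Normative cut-offs are lower-tail empirical quantiles with the
linear-interpolation (Hyndman–Fan type 7) definition, recorded in the
output metadata; at least 20 control values are required.  Cut-offs are
monotone across levels by construction — a published non-monotone ratio
cut-off sequence was judged a typographical artefact and is not
reproduced.

## Perimetric staging and the synthetic norm table

TD probability staging needs per-point thresholds; instrument norms are
proprietary.  The package therefore derives a synthetic table from its
own structure–function model: at each point, the TD stage at level k is
placed at the dB loss corresponding (via the 20 dB-per-unit-integrity
slope) to the ganglion-cell integrity at which the ONHC ratio crosses
its k-th stage boundary at the same eccentricity, then offset 0.4 of the
way into the next deeper stage's integrity band.  Two properties
motivated this over a fixed −4/−6/−8/−10 dB table:

1. *Consistency*: the overlap analysis compares two staging systems; the
   meaningful requirement is that they grade the same underlying loss
   equivalently, not that either matches a particular instrument.  The
   derived table makes a TD stage and its matched ratio stage refer to
   the same integrity band at every eccentricity (the healthy ONHC ratio
   is a step function over the rings' radial footprints: ~1.34 centrally,
   0.94, 0.87, then 0.63 beyond ~12°).
2. *Stability*: the 0.4-band nesting offset places each perimetric stage
   strictly inside its matched ratio stage's band, so the matched-stage
   overlap does not sit on a knife edge where sampling geometry (61
   hexagons vs 76 points) decides ties between adjacent stages.

The resulting thresholds are eccentricity-dependent and stricter
centrally, like real norms, but absolute agreement with any perimeter is
explicitly not claimed.  Analyses of real TD exports should supply the
instrument's own categories, which the reader accepts directly.

## Rasterization and the overlap statistic

Both staged maps are rasterized onto pixel centres at 0.1 deg/px over
±30° (601×601; configurable down to 0.25 deg/px).  Hexagon masks set a
pixel when its centre falls inside a flagged polygon; each flagged 30-2
point contributes its natural 6°×6° lattice cell (half-open edges, so
adjacent cells tile exactly), clipped to the circular 30° field.  The
overlap is 100·2|A∩B|/(|A|+|B|); when both masks are empty the cell is
undefined (NaN) and excluded from cohort means rather than counted as 0
or 100.  At 0.1 deg/px the hexagon raster area agrees with the exact
polygon area to well under 1%.

With one mask fixed and the other grown through it as a nested family,
this statistic rises to exactly 100% at equality and falls on either
side — the concave ("negative quadric") overlap curve.
`fit_overlap_quadric` performs the corresponding least-squares quadratic
fit, reports the vertex −b/2a, and flags non-concave or extrapolated
fits.  Group comparisons use the standard two-sample t-test (pooled by
default, Welch optional) and one-way ANOVA with Bonferroni-adjusted
pairwise post hoc t-tests (p_adj = min(1, m·p)).

Eyes contribute one matrix each; no within-patient eye averaging is
attempted, to avoid inventing a correlation structure.

## The synthetic-eye generator

A single scalar integrity field I(x, y) ∈ [0, 1] over the visual field
drives both modalities, which is exactly what makes closed-loop testing
possible: the defect seen by perimetry and the deficiency seen by the
mfERG derive from the same ganglion-cell damage.  Field coordinates are
used throughout; a superior-field defect *is* inferior retinal damage,
so the field↔retina vertical inversion is implicit and arcuate defects
never cross the horizontal raphe temporal to the disc (their weight is
hard-clipped to one hemifield).

**Waveforms.** Each hexagon's trace is a 1 nV/deg² resting offset plus
three Gaussian deflections sampled at 13.33/16 ≈ 0.83 ms over 128
samples: a direct-component deflection (30 ms, σ 2.5 ms, 20 nV/deg²,
unaffected by ganglion-cell loss), a first IC positive deflection
(61.5 ms, σ 2.5 ms, 10 nV/deg² when healthy) and the ONHC deflection
(σ 3.2 ms) at implicit time 70 ms + distance/velocity with velocity
1 m/s — placing all 61 latencies in ~70–83 ms, inside the epoch, with
the ONHC always the second positive peak by construction.  White
Gaussian noise (default SD 0.5 nV/deg²) is added.  Both IC deflections
scale with local integrity (the induced component is inner-retina
generated): the ONHC height as profile(ring)·I^2.0 and the first IC peak
with the same power law, so a dead patch silences the whole IC rather
than leaving a misleading first peak for the sole-maximum fallback to
return.  The healthy amplitude-density profile per ring is
(17, 12, 11, 8, 8) nV/deg², declining with eccentricity as control
recordings do; between-subject variability is a lognormal gain
(σ = 0.2).

**Exponent choice.** The integrity→amplitude exponent 2.0 was calibrated
jointly with the norm table (above) so that the four ratio-stage
boundaries fall at integrities ≈ 0.89/0.69/0.56/0.40 in the periphery —
spread widely enough that a graded defect produces four spatially
distinct stage bands, and reachable at the default defect depth 0.8
(core integrity 0.2).  With a linear mapping the deepest boundary
(I < 0.16) would be unreachable at that depth.

**Damage fields.** The default glaucomatous defect is an arcuate
(Bjerrum-region) band: radius 16° ± 1.5 (per-eye jitter), radial
half-width 14° with a full-depth core at 45% of the half-width and
linear shoulders, arcing 10°–170° (±5°) around the fixation with 70°
angular shoulders, in one hemifield.  The linear shoulders make the four
stage regions shrink roughly geometrically (~1.6× per stage), which is
what produces the clinically observed pattern in which each TD stage
overlaps its matched deficiency stage best.  Nasal-step and paracentral
defects are available with the same conventions.  Central sparing
(integrity floor 0.9 inside 8°) is on by default, mimicking the
preserved central field of mild-to-moderate disease — it is also why the
top-7 reference remains comparable between groups.  Hexagon integrity is
sampled at the element centre plus a quarter-scale vertex shell rather
than averaged over the full stimulus area, so both modalities sample the
field at comparable spatial support; full-area averaging would blur
defect borders across neighbouring stages relative to the point-sampled
perimetry.

**Perimetry.** TD = −20·(1 − I) dB (floor −30 dB) plus test-retest noise
(SD 1.0 dB); categories come from the shared norm table.  Cohorts draw
per-eye generators from a spawned seed sequence, so results are
reproducible from one master seed and independent of processing order.

**What the simulator does not emulate**: m-sequence stimulation and
kernel extraction (traces are synthesised directly), fixation losses and
blinks, inter-subject variation in disc position or axon trajectories,
instrument-specific norm shapes, floor effects of perimetric staircases,
and any correlation between fellow eyes.  Passing closed-loop tests
therefore demonstrates that the pipeline recovers what it is designed to
measure under its own signal model — not that clinical sensitivity or
specificity would match any particular cohort.

## Problem sizes in the test and acceptance runs

The closed-loop cohort check uses 30 glaucomatous eyes (superior arcuate,
depth 0.8) and 20 controls at default noise; the acceptance script runs
the default cohort of 39 glaucomatous eyes (random hemifield) and 30
controls.  Oracle comparisons use 200 random mask pairs at the full
601×601 raster, 500 random waveforms, and 100 random vectors for the
quantile and scale-invariance properties.

## Known limitations

- The second-peak rule identifies the ONHC by ordinal position; severely
  distorted waveforms in which the ONHC merges with the first IC peak
  are scored as a single peak, and the resulting amplitude is then the
  merged complex's height.
- The per-hexagon ratio saturates for advanced disease in which the
  central reference itself is depressed; a population-based normalisation
  via `normative_cutoffs` is provided but no reference population ships
  with the package.
- The bundle fibre-path model is a slit-plane geodesic, not an anatomical
  axon-trajectory atlas; it is adequate for monotone latency ordering,
  not for tracing individual bundles.
- Undefined overlap cells (both stages empty) are excluded from means;
  cohorts dominated by very mild disease can therefore have deep-stage
  summaries based on few eyes — the per-cell n is reported.
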