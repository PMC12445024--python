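# Methods

## Detection model

The pipeline formalises the classic ImageJ-style workflow for negative-stain
TEM: particles appear as bright cores on a mid-gray background, so candidate
particles are local maxima of the intensity surface. A maximum counts as a
seed when its prominence — its height above the saddle separating it from
higher terrain — exceeds the `noise_tolerance`. This is computed with the
h-maxima transform: morphological reconstruction of `image − h` under
`image` clips every maximum of prominence < h into its surroundings, and
each surviving maximum becomes exactly one flat dome-top plateau of the
reconstructed surface, however ragged its top is under noise. One seed is
placed per plateau, at the centroid of the plateau's peak-valued pixels
(snapped to the nearest plateau pixel; ties broken by row, then column).

Each seed then claims the connected set of pixels with intensity at or above

    background + seg_fraction · (peak − background),

where the background is the image median — robust because particles cover a
small fraction of a typical frame. Pixels reachable from two seeds are
divided by a marker-controlled watershed of the intensity surface, leaving a
one-pixel boundary line. Interior holes are filled at this stage: a
cup-shaped particle's dark central depression falls below the level but
belongs to the particle's projected outline, and without filling both its
area and its shape descriptors would describe an annulus. The fill is
confined to the seed's own watershed basin; this matters because a flat
background plateau is itself a regional maximum (its neighbours are the
darker stain rims), and its "holes" are the particles.

Surviving regions are filtered by physical area (inclusive bounds, nm²,
converted to pixels via the calibration), circularity, and optionally
border contact (on by default — partial particles bias sizes low). Each
retained region is summarised by its second-central-moment ellipse, rescaled
so the ellipse area equals the pixel area exactly.

Because the level-set never reaches into the dark rim, detected regions
correspond to the bright core, not the full particle: detected diameters
underestimate true outer diameters by roughly the core/outer diameter
ratio. This is a property of maxima-seeded detection on negative-stain
images, not of any particular image; the `validation` module quantifies it.

## Measurements

- **Area-derived diameter** d_A = √(4A/π), exact in floating point; a
  function of pixel count only, never of shape.
- **Linear (max-Feret) diameter**: the largest distance between any two
  boundary-pixel centers plus one pixel of extent, so a single pixel
  measures 1 px rather than 0. For regions with more than 400 boundary
  pixels the pair search is restricted to convex-hull vertices, which is
  exactly equal to the all-pairs maximum.
- **Circularity** 4πA/P² with the 4-direction Crofton perimeter estimate,
  capped at 1.05 to absorb discretisation overshoot on near-ideal discs.
  The Crofton estimator is multigrid-convergent on smooth shapes (discs
  land in [0.95, 1.05]) but underestimates the perimeter of axis-aligned
  rectangles (≈ π·mean 4-direction support width), so a square scores
  ≈ 0.90 rather than the ideal-polygon π/4 ≈ 0.785. We accept this: the
  filter's purpose is separating round particles from junk, and the
  disc behaviour is the calibrated one.
- **Cup-shape score** 1 − mean(I_inner)/mean(I_region), where the inner
  sub-region holds the 50% of region pixels closest to the centroid in the
  Mahalanobis metric of the region's second moments. Radially uniform
  (round) particles score ≈ 0; particles with a darker interior depression
  score higher; the default decision threshold is 0.15. The score is
  invariant to multiplicative intensity rescaling (it is a ratio of means)
  but deliberately not to additive offsets. Regions under 9 px return
  (0, not-cup). This classifier and its threshold are constructions of this
  package, tuned on the synthetic generator — the underlying distinction is
  made visually in practice.

## Synthetic scene generator

Each scene renders, per particle, an elliptical bright core of diameter
`core_fraction · d_true` at `core_contrast`× background, an annular stain
rim out to `d_true` at `rim_contrast`× background (darker than background),
an optional off-center elliptical interior depression for cup-shaped
particles (intensity between rim and background), additive Gaussian noise,
and quantisation to 8 or 16 bits. Edge ramps are smoothstep transitions one
pixel wide centered on the nominal outlines, so thresholding a noise-free
render midway between levels recovers the stated diameters; this is the
oracle the tests use. Placement is sequential rejection sampling with a
margin of d/2 + 2 px from the frame edge and, by default, non-overlapping
outlines (an overlap mode exists to stress watershed splitting). Everything
derives from a single integer seed; identical parameters give bit-identical
scenes.

Default parameters (one 512 × 512 px frame at 1 nm/px):

| parameter | default | rationale |
|---|---|---|
| diameter law | lognormal, mean 36 nm, SD 10 nm | matches the 20–80 nm range of plasma EVs; the right skew puts the histogram mode a few nm below the mean, as real EV size histograms show |
| n_particles | 25 | a typical well-populated frame |
| core_fraction | 0.74 | sets the rim share of the outer diameter, and hence a detected/true ratio near the ≈ 0.74 quotient observed between automated and manual sizing |
| core_contrast / rim_contrast | 1.5 / 0.75 | bright core, rim darker than background, on a 0.5 background level |
| cup_probability | 0.05 | cup-shaped particles are seen in 3–8% of particles in real preparations |
| noise_sd | 0.02 (of full scale) | mild shot/stain texture noise, ≈ 5 gray levels at 8 bits |

What the generator does **not** emulate: stain granularity and mottle
(noise is white Gaussian), electron-optical effects (defocus, CTF),
aggregation and overlapping clusters (off by default), intensity gradients
across the frame, and antibody decoration. Passing tests therefore
demonstrate correctness of the algorithmic chain against a controlled
optical model of negative stain, not performance on any particular
microscope's output; on real data the thresholds must be tuned per dataset.

## Detection defaults

`noise_tolerance` defaults to 30 gray levels: comfortably above the noise
floor (≈ 6 σ at the default noise level) and about half the core-to-
background amplitude of the default rendering, so every core is a seed and
single noise excursions are not. `min_size` 75 nm² and `max_size` 7850 nm²
bracket detected (core) sizes for true diameters of roughly 12–120 nm;
`min_circularity` 0.6 passes near-elliptical cores while rejecting ragged
noise regions; `seg_fraction` 0.5 delimits regions halfway between
background and peak. An optional Gaussian pre-blur (`gaussian_sigma`,
default off) is available for noisier data but makes no claim of fidelity
to any particular original workflow.

## Statistics

Sample SD uses the n−1 denominator throughout. Histogram modes use 1 nm
bins anchored at integer multiples of the bin width, leftmost bin on ties,
reported as bin centers. Band filters are inclusive at both endpoints.
Welch's test from summary statistics uses the Welch–Satterthwaite degrees
of freedom; two zero-variance samples with equal means return p = 1 by
convention (p = 0 when means differ). Automated/manual quotients are
reported rounded to 3 decimals; no multiple-testing correction is applied
(comparisons are reported with raw p-values). The mean-diameter comparison
between the two diameter estimators uses a paired t-test and reports the
mean difference and the percent change relative to the linear estimate.

Note on estimator ordering: for convex regions the max-Feret diameter is
necessarily ≥ the area-derived diameter (up to one pixel of
discretisation). Hand-drawn "edge to edge" lines are not guaranteed to be
maximal calipers, so manual linear measurements can come out *smaller* than
area-derived ones even where max-Feret would not; this package reports both
estimators and does not attempt to reproduce manual measurement behaviour.

## Reproducibility and the CLI

Every subcommand writes a `manifest.json` with the resolved configuration,
seed, input and output lists. Repeated runs with identical arguments are
byte-identical, including the manifest: the manifest's timestamp field is
null unless `--stamp` is passed, a deliberate trade of provenance detail
for verifiable determinism. The `measure` subcommand re-scores cup shape on
existing CSV tables; since masks are not serialised, each particle's region
is reconstructed as its fitted-ellipse pixel set, which slightly smooths
the region relative to the original mask.

## Problem sizes

The validation experiments use 512 × 512 px scenes at 1 nm/px: 20 scenes of
25 particles for detection precision/recall, and two cohorts of 10 scenes
at ~30 particles (true means 35 and 38 nm, shared core fraction 0.74) for
the bias experiment — together a few hundred particles per experiment,
enough that binomial noise on the reported rates is ≈ 1–2%. The 2SD
coverage check uses 10⁵ Gaussian draws.

## Known limitations

- Touching particles are split by a single watershed line; heavily
  overlapping aggregates are not resolved into constituents.
- Calibration must be supplied; there is no scale-bar reading, and the
  shipped magnification table is a generic starting point the user should
  edit for their detector.
- The cup classifier depends on interior contrast and will miss cups whose
  depression is shallower than the decision threshold.
- Size thresholds are interpreted on the *detected* (core) region, which is
  smaller than the true particle; users thinking in true diameters should
  scale bounds by the expected core fraction.
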