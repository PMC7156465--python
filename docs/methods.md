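# Methods

This note documents the models, conventions and numerical choices
behind `iomorph`: what each operator computes, what the synthetic
forearm phantom does and does not emulate, and where the design was
genuinely open.

## Coordinate and unit conventions

All geometry is in millimetres, forces in Newtons, angles in degrees,
strains in percent.  Meshes, landmarks and curves must share one
coordinate frame; no particular frame is assumed, only a common one.
Bone axes are oriented distal → proximal.

## Morphometric operators

### Bone axis

The longitudinal axis of a long bone is the first principal component
of its mesh vertex cloud, oriented by a caller-supplied *distal hint*
(any point nearer the distal than the proximal end).  Anatomical-
standard axis definitions depend on landmarks we do not require; for
shaft-dominated meshes the principal axis is a reproducible surrogate
and is exact for the phantom's cylinders.  Meshes whose largest/second
principal extent ratio is below 1.5 are refused as degenerate.  The
distal point is the vertex extremal against the axis; the bone length
is the extent of the vertex projections.

### Fan-out angle and its sign

The angle magnitude is the acute angle between the fibre *line* and the
radius axis *line*, computed as `atan2(|u⊥|, |u·a|)` (numerically
stabler near 0° and 90° than the arccos form, against which it is
verified to 1e-9°).  Magnitude alone cannot distinguish a CB-type from
a DOAC-type course, and connecting the published attachment
percentages gives obtuse arccos values for CB-type fibres, so a sign
convention is attached: **positive** when the radial→ulnar vector has a
distally directed component along the axis (radius-origin CB/AB
fibres), **negative** when proximally directed (ulna-origin DOAC/DOB),
exactly 0 for parallel vectors and +90° for perpendicular ones.

### Ligament separation

Each four-clip ligament is cut from the membrane by two planes, one
through each of its boundary fibre lines (p and d).  The plane normal
is the component of the radius axis orthogonal to that fibre, so the
plane contains both the fibre line and the dorso-palmar direction and
the two planes fan with the fibres.  The DOAC, annotated only at its
mid fibre, is cut by two parallel such planes separated by twice
`doac_clip_half_width` (default 4 mm, the clip length scale).
Triangles crossing a plane are cut exactly at the intersection (trimesh
plane slicing), never dropped, so clipped areas are conserved; the cut
boundary is left open (no cap triangulation), which none of the
downstream measurements require.

### Thickness profiles

A profile is measured inside a slab of total width `slab_width`
(default 0.2 mm) centred on the plane that contains the anchor, the
profile direction and the sheet's dorso-palmar direction.  Surface
points are collected from exact mesh cross-sections at five parallel
planes spanning the slab (resampled along the section polylines at half
the station step) plus any mesh vertices inside the slab, binned along
the profile direction at `station_step` (default 0.05 mm); per bin the
thickness is the maximum point-pair separation along the local vertical
(the direction orthogonal to both the profile direction and the slab
normal).  Bins with fewer than two points are reported **missing**,
never zero — zeros would bias pooled means.

The dorso-palmar ("vertical") direction of a clipped ligament is
estimated as the dominant eigenvector of the area-weighted face-normal
covariance `Σ area_f · n̂_f n̂_fᵀ`: the two broad faces of a thin sheet
dominate its area, so their common normal wins regardless of the
sheet's in-plane proportions.  (A vertex-PCA smallest axis fails for
narrow band-like pieces such as the DOAC, whose cross-band extent can
be smaller than its thickness; weighting by area — not squared area —
matters because edge walls have few but large triangles.)

Per ligament, profiles are taken along each fibre (p, mid, d; only the
mid fibre for the DOAC) and along the bone-axis direction through each
fibre midpoint; the ligament's mean/SD/range thickness pools all
non-missing stations of both directions.

### Attachment mapping

An insertion point's location is its projection on the owning bone's
axis, as % of bone length from the distal end, clamped to [0, 100] with
a warning beyond ±1 %.  Attachment width is read literally as the
*longitudinal* (axially projected) distance between the p and d
insertion points; a Euclidean-chord alternative is exposed as the
`width_metric` config switch rather than decided silently.

## Tensile-curve analysis

Strain is grip-to-grip: displacement over the initial gauge length (no
optical tracking is assumed).  Pre-conditioning cycles are expected to
be removed before analysis; `trim_preconditioning` drops any leading
cyclic segment by detecting displacement reversals.

* **Preprocessing** zeroes displacement at the first sample reaching
  the preload (default 0.5 N) and truncates after the force first falls
  below `failure_stop_fraction` (default 0.95) of the maximum, past the
  global maximum — the machine's stop criterion.
* **Linear region**: every contiguous window ending at or before the
  global force maximum and spanning at least `linear_fit_min_span`
  (default 0.1) of the pre-peak strain range is fitted by OLS; the
  window with the highest r² wins (positive slopes only; exact ties go
  to the widest window, then the earliest).  The minimum span keeps the
  search off short locally-linear stretches of the nonlinear limbs; 0.1
  is small enough that the genuinely linear region of every bundled
  reference-magnitude curve shape is admissible.  Windows are scored
  with prefix-sum statistics (O(1) per window).  If no window reaches
  r² ≥ 0.9 a poor-linearity warning is emitted and the best window is
  still returned — robustness over silent failure.
* **Peaks**: the ultimate force is the global maximum and the ultimate
  strain the strain at that sample.  The first fibre-failure peak is
  the earliest local maximum followed, before the global maximum, by a
  relative force drop of at least `first_peak_drop` (default 5 % —
  large enough to ignore noise wiggles at the generator's noise scale,
  small enough to catch genuine fibre-failure drops); monophasic curves
  report the ultimate force as the first peak.
* **Trapezoid CSA**: `(width_radial + width_ulnar)/2 × mean thickness`;
  nominal stress is force over this initial CSA.  Elastic moduli are
  deliberately not reported: the constant-CSA approximation would make
  them misleading, whereas stiffness comes straight from the
  force–displacement curve.

## The synthetic forearm phantom

The phantom exists so that every morphometric quantity has an *analytic*
truth value.

* **Bones** are straight capped cylinders (defaults: radius 254.4 mm,
  ulna 271.5 mm — the cadaveric mean lengths — with 9 and 8 mm shaft
  radii), parallel, separated by a configurable interosseous gap
  (default 16.4 mm, which puts the CB fan-out near the published
  20–35° range).
* **The membrane** is a watertight thin solid around a ruled
  mid-surface spanning the gap.  The mid-surface is built from fibre
  "rails" (one per annotated fibre): each ligament contributes its d
  and p fibres (the DOAC its mid fibre plus two flanking rails at
  ±4.5 mm perpendicular distance, making the cord a band of uniform
  thickness); margin rails extend the sheet 5 mm (perpendicular)
  beyond the extreme fibres.  Thickness is declared per ligament as a
  constant or a radial→ulnar linear ramp and interpolated linearly
  between rails, so offset surfaces represent the field exactly at any
  mesh resolution.  Rails must be strictly ordered on both bones;
  overlapping ligament spans are a configuration error.
* **Landmarks** are placed exactly at the analytic attachment-span
  endpoints; fibre geometry is therefore resolution-independent.
* **Spans vs angles.**  With spans declared on both bones, the fibre
  angle is geometrically determined, and the truth echoes the realized
  analytic angle.  A ligament may instead declare a signed fan-out
  angle (the DOAC default, −18.7°), from which the ulnar attachment is
  derived so the declared angle holds exactly.  Because group-mean
  attachment values of different specimens need not form one consistent
  geometry, the default AB span is shifted distally from its group-mean
  location (keeping its published widths) so it does not overlap the
  CB; the default DOB keeps its published spans, which across parallel
  cylinder bones yield near-perpendicular fibre angles — the truth echo,
  not the published group mean, is the recovery target.
* An optional seeded random rigid transform re-orients the whole
  phantom; all morphometric truths are invariant under it.

What the phantom does **not** emulate: curved bone shafts and
anatomical cross-sections, membrane curvature and fibre waviness,
segmentation/registration noise on real micro-CT meshes, and partial or
missing structures.  Passing recovery tests therefore demonstrates the
correctness of the measurement operators on clean geometry — not
robustness to segmentation artefacts, which must be judged on real
data.

## Synthetic tensile curves

Curves are generated in the machine frame that starts at the preload
(force(0) = preload exactly), with gauge length defaulting to 250 mm —
the grip-to-grip length of a mounted radius–membrane–ulna construct,
which is what makes stiffness ~20–160 N/mm, failure forces ~45–330 N
and ultimate strains ~1.3–6 % mutually consistent.  Shape, in order:

1. a concave quadratic toe over `toe_span` (default 0.5 mm — most of
   the physiological toe is taken out by the preload), joining the
   linear segment with continuous value and slope;
2. a linear segment at the declared stiffness, by default ending where
   the force reaches 90 % of the first peak (an explicit `linear_span`
   may be given instead);
3. a C1 softening limb (cubic Hermite, slope decaying from the
   stiffness to zero, mean slope `softening_fraction`·k, default 0.4)
   to the first fibre-failure peak;
4. a sharp 20 % drop — the thin-fibre failure event;
5. a concave re-engagement limb (Hermite, start slope 1.2× its mean) to
   the ultimate force at `gauge × ultimate_strain/100`;
6. a terminal decay to 35 % of the ultimate force, far below the 95 %
   stop criterion.

Monophasic curves (first peak = ultimate) use a single softening limb
whose linear span is additionally derived so the closing Hermite cannot
overshoot.  Samples every 0.005 mm (a 30 mm/min ramp logged at 100 Hz);
i.i.d. Gaussian noise of declared SD is added to force under the
declared seed.  Inconsistent parameter sets — a peak inside the toe, a
first peak below the linear-region end force, no room for the
re-engagement limb — are configuration errors, not silently repaired.

The curve shape is deliberately never steeper than the linear region
(softening after the linear range, concave re-engagement): this is the
physiological expectation, and it is also what makes an automatic
max-r² window search identify the true linear region under noise.

## Study-condition samplers

`sample_phantom_truths` draws geometries at the published magnitudes
(bone lengths 230–291 mm, gap 14–20 mm, spans jittered ±2 percentage
points around the defaults, thickness constants/ramps in 2–7 mm, DOAC
angles −25…−14°), rejecting draws with overlapping rails.
`sample_tensile_truths` draws curve *shapes* first (toe/linear/
softening/re-engagement spans as fractions of the failure displacement)
together with target ultimate forces (45–330 N) and strains
(1.3–6.2 %), deriving the stiffness — real curves couple these
parameters, and independently drawn combinations are frequently
unbuildable or physically nonsensical.

Default suite sizes — 20 phantoms at 2 mm mesh resolution, 50 curves
per tensile condition — were chosen as the smallest suites that
exercise every ligament type and curve shape while keeping the whole
validation run in the tens of seconds on one CPU.

## Aggregation conventions

Tables report mean, **population** SD (divisor n) and range.  The
population convention is used because it exactly reproduces the SD
cells of the bundled five-forearm reference rows, while the sample
(n−1) convention demonstrably does not — this contrast is a unit test.
Single-specimen groups report SD and range as missing (a lone DOB
carries no dispersion information).  Display rounding is decimal
half-up at two decimals (one for strain columns, whose source values
carry one effective decimal); JSON outputs keep full precision.

## Known limitations

* The bone-axis surrogate (PCA) can differ from landmark-based
  anatomical axis definitions on strongly bowed radii; attachment
  percentages inherit that difference.
* Thickness is an outer dorso-palmar extent; internal voids or folded
  membranes (e.g. a DOB folded in supination) read as thicker than the
  tissue itself.
* The linear-region search assumes the curve is nowhere steeper than
  its linear range; grossly non-physiological curves can defeat the
  max-r² criterion (they are flagged by the r² < 0.9 warning).
* The pipeline assumes co-registered inputs; no registration is
  performed.
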