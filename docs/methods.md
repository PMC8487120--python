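# Methods

## Scene model and coordinate conventions

A `VesselScene` couples a 3-D integer label volume (0 background, 1 aorta,
2 LCCA, 3 LSA) with per-vessel centerline polylines, all in one physical
frame: LPS patient coordinates (+x patient-left, +y patient-posterior,
+z patient-superior), millimetres. The voxel-index→mm mapping is restricted
to the axis-aligned affine `x = index·spacing + origin`; oblique NIfTI
affines are rejected rather than resampled, because the projector assumes
an axis-aligned grid. Centerline files store physical mm, not indices, so
volume and curves share one frame without bookkeeping.

## Projection model

The C-arm sweep is a single rotation about the superior–inferior axis
(pure LAO; θ = 0 is the AP view), with zero cranial/caudal angulation:

    ray(θ) = (sin θ, cos θ, 0),  u(θ) = (cos θ, −sin θ, 0),  v = (0, 0, −1).

Projection is parallel-beam (orthographic). The X-ray source of a C-arm is
far from the aortic arch relative to the arch's size, so ray divergence
changes silhouettes only marginally; the orthographic model in turn admits
closed-form oracles (a sphere projects to a disk of exactly πr², a segment
at angle α to the ray foreshortens by exactly sin α). The geometry object
is self-contained, leaving room for a cone-beam variant later.

Silhouettes are computed by ray casting: a detector pixel is set iff the
parallel ray through its centre passes a voxel of the queried label,
sampling the ray at **half the minimum voxel spacing** with
nearest-neighbour lookup. This cannot skip a voxel, is deterministic, and
its geometric error is bounded by the sampling step. The default pixel size
is the minimum voxel spacing; the detector is sized from the scene's
bounding sphere plus a 2-pixel margin and centred on the projected scene
centre, so one detector shape covers the whole sweep. Rendered views
(`render_view`) are ray-path thickness maps normalised to [0, 1] — a
qualitative display, not an attenuation model.

## Per-angle metrics

**Overlap** is exact integer pixel counting on the two branch silhouettes:
`n_inter / (n_LCCA + n_LSA)`, in [0, ½]. Zero is compared exactly — a
meaningful operation only because the counts are integers. If both
silhouettes are empty the ratio is 0/0; we define it as 0 with a logged
warning, since an empty silhouette obscures nothing.

**Foreshortening** treats the delivered centerline as a polyline and sums
per segment. The numerator is the detector-plane component
`‖t − (t·P̂)P̂‖` of each segment `t` (equivalently the 2-D arc length of
the projected polyline), so the rate is 1 in a foreshortening-free view and
`sin α` for a straight segment at angle α to the ray. The along-ray reading
`Σ|t·P̂| / Σ|t|` — which is *maximal* when foreshortening is worst — is
kept selectable (`numerator="along_ray"`) for auditing, but everything
downstream maximises the detector-plane rate, which is the quantity the
"full display of the arch" requirement actually needs. No resampling is
applied to the polyline; the evaluated extent is exactly the centerline the
caller provides.

The sweep grid defaults to 0–90° inclusive in 1° steps, matching the
granularity at which clinical C-arm angles are actually set.

## Selectors

The **standard** baseline minimises `P_overlap + (1 − P_fs)`. The naive sum
`P_overlap + P_fs` (selectable as `variant="literal"`) would reward
foreshortening under the length-ratio definition of `P_fs`; the corrected
form expresses the evident intent of jointly minimising overlap *and*
foreshortening. Ties break to the smallest angle.

The **adaptive** selector applies set logic: θ_no-overlap = angles with
exactly zero overlap; θ_fsmin = smallest angle attaining the maximal rate
P_fsmax (ties to the smallest angle); the candidate set is {θ_fsmin} when
θ_fsmin ≤ 50°, `{θ : P_fs > 0.98·P_fsmax}` when 50° < θ_fsmin ≤ 60°, and
`{θ : P_fs > 0.95·P_fsmax}` when θ_fsmin > 60° (strict inequalities); the
result is the minimum of the intersection with θ_no-overlap. The tier
cut-offs encode a clinical preference: steep gantry angles are awkward to
work under, so when the best-display angle is steep, a small tolerance on
the display quality buys a meaningfully shallower view.

The set logic alone is partial — the intersection can be empty, and the
singleton tier can miss θ_no-overlap entirely. A fallback ladder makes the
selector total while keeping overlap avoidance dominant: (1) widen the tier
tolerance step by step (98 %, then 95 %, then any overlap-free angle,
preferring maximal P_fs, ties to the smaller angle); (2) only if *no*
overlap-free angle exists, take the angle with minimal overlap (ties:
larger P_fs, then smaller angle). The branch taken and any fallback are
recorded on the result and logged. An invariant follows: whenever an
overlap-free angle exists on the grid, the selected angle has exactly zero
overlap — the guarantee joint minimisation cannot give.

Angles are reported on the grid; no sub-grid interpolation is done.

## The synthetic phantom

`PhantomSpec`/`generate_phantom` build the geometry the planner assumes: a
semicircular arch midline of radius `arch_radius` in a plane containing the
z-axis whose normal points along LAO `arch_plane_lao`, straight ascending
and descending limbs (C¹ joins), and two straight branch cylinders leaving
the arch midline at `branch_angular_positions` (degrees along the arc).
Everything about it is oracle-friendly: the aortic centerline length is
π·R + ascending + descending in closed form, the arch plane is known
exactly, and the centerlines are analytic (sampled at 1 mm, well below
voxel spacing). Voxelisation labels a voxel by distance to the nearest
tube axis (aorta wins over branches; between branches the nearer axis wins,
LCCA on exact ties).

Branches are tilted out of the arch plane by `branch_axis_tilt`: a scalar t
means opposite signed tilts (−t for LCCA, +t for LSA); a pair is taken
literally. Opposite tilts are the control dial for overlap: viewed
perpendicular to the arch plane the out-of-plane divergence is invisible
and the branches appear maximally separated, while sweeping *below* the
arch-plane angle makes the projected axes converge and overlap. With the
default geometry the overlap band ends a few degrees below the arch-plane
angle — i.e. the no-overlap set has a lower edge that tracks the
patient-specific arch orientation, which is precisely the regime the
adaptive selector exists for.

Defaults (mm, degrees): arch radius 30, aorta tube radius 11, branch
radius 3.5, branch positions (81, 99), branch length 45, tilt 65,
ascending 60, descending 70, arch plane LAO 45, grid 96³ at 2 mm — adult
thoracic proportions at CT-like resolution, with the arch plane at the
LAO angle experts typically choose for deployment views. Cohorts
(`sample_cohort`) add seeded uniform per-field jitter; the default ranges
(`DEFAULT_COHORT_JITTER`) draw the arch plane from LAO 35–55° and vary
radius, limb lengths, branch length and branch positions mildly while
keeping each draw inside the grid (invalid draws are rejected and redrawn,
capped at 100 attempts).

What the phantom does *not* emulate: non-circular arch curvature, vessel
tapering, dissection lumina, contrast dynamics, detector noise and
cone-beam magnification. Tests passing on the phantom therefore validate
the geometry pipeline and the selection logic — the projector, the metric
definitions, set logic, tie-breaks and fallbacks — not robustness to
segmentation error or to anatomy far from the tube-and-arc idealisation.

## Statistics

`compare_angle_sets` mirrors the usual evaluation of a method against a
reference: Shapiro–Wilk on both samples at the same α as the significance
level (0.05 by default); two-sided unpaired Student's t-test when both pass,
two-sided Mann–Whitney U otherwise. Tests are unpaired because group means
are compared; the per-case absolute differences and their proportions in
[0, 3), [3, 5) and [5, ∞) degrees (left-closed, right-open) are a separate
paired summary. Both SD and SEM are reported, since summaries written as
mean ± spread are ambiguous between the two.

## Numerical choices and degenerate inputs

- Exact zero-overlap comparison is justified by integer pixel counting;
  profile CSVs round-trip zeros exactly.
- Tier comparisons are strict (`>`), as defined; argmax/argmin ties break
  to the smallest angle throughout.
- Empty branch silhouettes ⇒ overlap 0 with a warning (see above).
- Coincident branch origins are permitted (the two tubes then share their
  take-off point); exact labelling ties go to LCCA.
- Zero-length centerlines cannot be constructed (consecutive duplicate
  points are rejected at the type level).
- Translating a scene along the ray direction leaves silhouettes
  bit-identical; this falls out of deriving the ray-sampling interval from
  the projected label bounding box.

## Problem sizes

Default phantoms voxelise to 96³ (2 mm); the unit-test phantom uses 64³
(2.5 mm), where a full 91-angle sweep takes well under a second. The
cohort evaluation uses 20 phantoms at the default size; selector/oracle
cross-checks use 1000 randomised profiles and the statistics calibration
1000 replicates of n = 30 — sizes at which every quantity is stable yet
the complete acceptance run finishes in about half a minute on one CPU.

## Known limitations

- Single-axis sweep only: no cranial/caudal angulation, no RAO extension;
  the optimal view is constrained to the 0–90° LAO arc.
- Parallel-beam projection ignores magnification differences across depth.
- The overlap metric counts the full labelled branch regions; it does not
  restrict to the supra-arch segments nor consider branch-versus-arch
  overlap.
- The foreshortening metric is evaluated on whatever centerline extent the
  caller supplies; planners wanting arch-only foreshortening should crop
  the centerline accordingly.
- Phantom realism is deliberately limited (see above); clinical use would
  feed segmented CTA labels and extracted centerlines, whose quality this
  package does not assess.
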