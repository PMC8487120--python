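# arcview

Automatic C-arm viewing-angle planning for thoracic endovascular aortic
repair (TEVAR), computed from a pre-operative 3-D scene instead of
intra-operative trial and error.

During TEVAR the stent graft is deployed under 2-D angiographic guidance.
The gantry angle chosen for that view matters twice over: the projections of
the left common carotid artery (LCCA) and the left subclavian artery (LSA)
must not overlap (or the operator cannot see which branch the stent is
about to cover), and the aortic arch should be displayed with as little
foreshortening as possible. Finding that angle by repeated contrast runs
costs radiation and contrast agent. `arcview` simulates the angiographic
view for every C-arm angle in the 0–90° LAO sweep from a labelled 3-D
volume (e.g. segmented CTA) plus the aortic centerline, scores each angle,
and selects the optimal one automatically.

## Method

For each sweep angle θ the scene is projected with a parallel-beam
geometry. Two per-angle scores are computed:

- **Projection overlapping rate** (POR), from the binary branch silhouettes
  by exact pixel counting:

  P_overlap(θ) = NP[S_LCCA(θ) ∩ S_LSA(θ)] / (NP[S_LCCA(θ)] + NP[S_LSA(θ)])

  where NP counts set pixels; the rate lives in [0, ½] and is 0 exactly
  when the branches are clear of each other.

- **Projection foreshortening rate** (PFR), the ratio of the projected
  aortic centerline length to its 3-D length:

  P_fs(θ) = T₁(θ) / T₂,  with P_fs = 1 meaning no foreshortening.

Two selectors consume the resulting angle profile:

- **standard**: argmin over θ of P_overlap(θ) + (1 − P_fs(θ)), the joint
  minimisation baseline (no overlap-freedom guarantee);
- **adaptive**: collect θ_no-overlap = {θ : P_overlap(θ) = 0}; find
  θ_fsmin, the smallest angle attaining P_fsmax = max P_fs; keep
  {θ_fsmin} if θ_fsmin ≤ 50°, else every θ with P_fs > 98 % of P_fsmax
  (50° < θ_fsmin ≤ 60°) or > 95 % (θ_fsmin > 60°); the optimal view is the
  minimum of the intersection with θ_no-overlap. Large gantry angles are
  clinically awkward, so a flatter tolerance buys smaller workable angles
  while overlap freedom stays a hard constraint.

A parametric aortic-arch phantom (semicircular arch plus straight limbs and
two branch cylinders, with analytically known arch-plane orientation and
centerlines) makes every stage testable without patient data. See
`docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from arcview import PhantomSpec, generate_phantom, select_for_scene

spec = PhantomSpec(arch_plane_lao=52.0)          # ground truth: 52 deg LAO
scene = generate_phantom(spec)
adaptive, standard, profile = select_for_scene(scene)

print(f"theta_fsmin = {adaptive.theta_fsmin:.0f} deg, "
      f"P_fsmax = {adaptive.p_fsmax:.4f}, tier branch: {adaptive.branch}")
print(f"adaptive optimal view : {adaptive.theta_optimal:.0f} deg "
      f"(fallback: {adaptive.fallback_used})")
print(f"standard joint minimum: {standard.theta_standard:.0f} deg")
```

prints

```
theta_fsmin = 52 deg, P_fsmax = 1.0000, tier branch: 50-60
adaptive optimal view : 48 deg (fallback: none)
standard joint minimum: 52 deg
```

The arch plane of this phantom faces LAO 52°, so foreshortening is minimal
there (P_fsmax = 1 at θ_fsmin = 52°). Because 52° falls in the 50–60° tier,
the adaptive selector admits every overlap-free angle whose PFR is within
98 % of the maximum and takes the smallest — 48°, a shallower, clinically
friendlier view that still shows the arch essentially in full and keeps the
branches separated. The standard selector sits at the joint minimum, 52°.

The same pipeline is available from the shell:

```sh
arcview phantom --out bundle/            # write a synthetic scene bundle
arcview sweep  --scene bundle/ --step 1.0 --out profile.csv
arcview select --scene bundle/ --out selection.json
arcview evaluate --results method.csv --reference expert.csv --out report.json
```

Scene bundles are plain formats: a NIfTI label volume (background/aorta/
LCCA/LSA), CSV centerlines (`x_mm,y_mm,z_mm`, LPS millimetres), and a JSON
label map.

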