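# Methods

## Scope and model

`aneuflow` covers the post-processing side of intracranial-aneurysm flow
analysis: given a vessel tree (centerline anchors, junction topology,
outlet cross-sections) it assigns per-outlet flow fractions under five
strategies, and given a time-resolved velocity/WSS field on a labeled mesh
it computes the standard intra-aneurysmal flow and shear metrics. Solving
the 3D Navier–Stokes problem is out of scope; the fields the metrics
consume come either from an external solver export (ASCII VTU series) or
from the package's analytic phantoms.

## Raytraced luminal area

The anatomical splitting strategy (`bc5`) needs the true lumen area of a
segmented, generally non-circular border. `polygon_area_raytrace` casts
`n_rays` rays from the centerline anchor, uniformly spaced in angle within
the section plane, intersects each with the boundary polyline, and returns
the area of the fan polygon through the hit points.

Numerical choices:

- **Ray phase** — the first ray is the projection of the global +x axis
  onto the plane (+y if degenerate), so results are reproducible and
  independent of boundary vertex order.
- **Ties and non-convexity** — the nearest positive intersection is taken.
  This is continuous in the inputs and makes the recovered polygon
  star-shaped around the anchor, which is exactly what "rays from the
  centerline to the border" implies; borders that are non-star-shaped
  around the anchor are silently regularised to their visible region.
- **Default `n_rays = 64`** — the area error for a circular section is
  `(2π²/3)/n²` relative, i.e. < 0.1% at 64 rays. The error is O(n⁻²) and
  monotone from below for convex borders (asserted by tests).
- The anchor must lie inside the border and the border within a planarity
  tolerance (default 1e-6 mm) of the section plane; both are validated.

Areas are bridged to the diameter-based strategies via the equivalent
diameter `D = 2√(A/π)`. For sections supplied as radii the closed forms
are used directly.

## Splitting strategies

`bc2`/`bc3` use the *normalised* power law `f_i = D_iⁿ/Σ D_jⁿ`. The power
law is a proportionality statement; the normalised form is the only
reading that conserves mass over more than two outlets, and it reproduces
the internal n = 2 ↔ n = 3 consistency of published split tables at three
decimals.

`bc4`/`bc5` traverse the tree: at each junction the children receive local
fractions proportional to `D²` (respectively the raytraced `A`), and an
outlet's global fraction is the product along its root path. Junctions
with more than two children are split jointly (pairwise ratios and joint
proportionality coincide). Single-child nodes pass flow through unchanged.
On a one-junction tree `bc4` coincides with `bc2` exactly (regression
tested on random trees).

`bc1` (zero pressure) is fundamentally a property of the 3D solution; a
desk-scale stand-in is provided as a 0D Poiseuille network: each segment
is a resistor `G = πR⁴/(8μL)` (blood viscosity μ = 0.004 Pa·s by default),
a unit flow enters the inlet, all outlets are grounded, and nodal analysis
gives the outlet flows. This surrogate is labeled as such throughout; it
shares the qualitative behaviour of the zero-pressure condition
(resistance-dominated splits, strong R⁴ sensitivity) but is never claimed
to reproduce a transient 3D solver's split.

## Hemodynamic metrics

All temporal integrals are trapezoidal on the supplied samples of one
cycle (second-order on smooth fields; exactly periodic samplings integrate
zero-mean harmonics to machine zero). Spatial means are volume-weighted
over tetrahedra for volume quantities and area-weighted over wall
triangles for shear quantities, making results insensitive to local mesh
refinement. Point-defined quantities (OVI) are averaged with lumped
volume weights (each tet spreads a quarter of its volume to each vertex).

- **Vorticity** uses a weighted least-squares gradient fit over the k
  nearest neighbours (k = 24 by default, inverse-distance weights), exact
  for affine fields. Coplanar neighbourhoods (possible on structured
  meshes with tied distances) are widened automatically before erroring.
- **OVI** uses the velocity *vector* in the numerator: the scalar-speed
  reading is identically zero, and the documented upper bound 0.5 is only
  reachable through vector cancellation. Points whose cycle speed
  integral vanishes are assigned OVI 0 (trivially steady). The index is
  invariant under positive rescaling of the velocity and needs no
  clamping: the triangle inequality bounds it in [0, 0.5].
- **KER** is the ratio of time-averaged sac KE to time-averaged parent KE
  (time average of the ratio would be a different, noisier statistic).
- **LSA** uses the area-weighted parent SD, consistent with the
  area-weighted parent mean that defines the threshold; the inequality is
  strict (`TAWSS < boundary`).
- **WSS from velocity** (when a series carries no WSS): the gradient at
  wall vertices is reconstructed with a weighted *quadratic* fit — wall
  neighbourhoods are one-sided, and an affine fit systematically
  under-predicts the wall gradient of a parabolic profile (≈20% at the
  default mesh), while the quadratic fit is exact for linear shear and
  for Poiseuille profiles up to surface-polygonisation error (≈1%
  measured, tested against the 4μV̄/R closed form at 5%).
- **Mean vorticity** is reported as the mean vorticity *magnitude* (the
  alternative — mean of a signed component — depends on an arbitrary
  axis; magnitude is the axis-free reading).

Parent-vessel extent and sac/parent labels are caller-supplied (region
arrays or the `region` cell array in VTU input); the package does not
locate the ostium itself.

## Synthetic data

`make_tree` builds deterministic bifurcating trees: leaves carry circular
sections with the requested radii, internal radii follow the Murray
closure `r_parent³ = Σ r_child³`, and the branching pattern is balanced or
caterpillar. Segment length defaults to 10 mm.

`make_ensemble` emulates inter-operator segmentation scatter: each member
applies (i) a global over/under-segmentation scale factor drawn from
`scale_range`, (ii) per-section radius jitter (relative SD
`radius_noise_sd`), and (iii) smooth low-order radial roughness (Fourier
modes 2–6), all from one seeded generator stream; member 0 is always the
unperturbed base. Defaults (±5% scale, 3% radius SD, 2% roughness) are
chosen to resemble the scatter reported between human operators
reconstructing the same lumen; the generator reproduces that *statistical
structure* only — it does not model imaging physics, surface steps or
topology errors, so passing tests bound arithmetic and convergence
behaviour, not image-segmentation realism.

`make_phantom` produces analytic fields on tetrahedral meshes (structured
cylinder and Fibonacci-shell sphere clouds, Delaunay-connected) together
with a *prescription record* of closed-form metric values computed
independently of the metric code (closed forms, dense quadrature):

- `poiseuille` / `pulsatile_poiseuille` — axial profile
  `u_z = V(t)·(2(1 − r²/R²) + ε)` with a small analytic slip ε = 0.02.
  The slip is a deliberate phantom-design choice: with a strict no-slip
  profile the wall nodes carry identically zero velocity for the whole
  cycle, score OVI 0 by convention, and drag the spatial mean of a
  perfectly reversing field measurably below the ideal 0.5 at any
  resolution. With the slip, every node oscillates and the reversing-flow
  prescription OVI = 0.5 is attained exactly, while the profile's spatial
  moments (`⟨shape⟩ = 1 + ε`, `⟨shape²⟩ = 4/3 + 2ε + ε²`) and the wall
  shear `4μV(t)/R` remain closed-form.
- `rigid_rotation` — `u = Ω(−y, x, 0)`, prescription vorticity 2Ω.
- `sac_on_pipe` — plug-flow parent pipe plus a spherical sac carrying the
  twisted uniform-speed field `s·(cos kz, sin kz, 0)`: the speed is
  uniformly `s = speed_ratio·V` (so KER = speed_ratio² with no
  direction-averaging bias) and the vorticity magnitude is the uniform
  `s·k`. Sac WSS magnitude is prescribed directly, optionally graded
  axially so the low-shear area becomes a continuous spherical-cap
  fraction with a closed form.

Default problem sizes (pipe 2 mm × 8 mm at 8×20×32 resolution, ≈5 000
points; 33 samples per cycle) keep the full phantom suite under a minute
while holding discretisation error within the round-trip bands the tests
assert (≤2% on volume means, ≤1% on KER, ≤5% on velocity-derived TAWSS,
exact OVI endpoints).

## File formats

Trees are YAML (nodes, segments, units header, default mm) with section
borders in sidecar x,y,z CSVs; fields are ASCII VTU series (one file per
step, `velocity` point array, optional `wss`/`region` cell arrays,
`TimeValue`/`Density`/`Viscosity` field data) plus a `regions.yaml`
sidecar; geometry is mm, physics SI. The VTU support is written against
the ASCII `UnstructuredGrid` subset the package emits. STL surfaces are
read through `trimesh`.

## Known limitations

- The `bc1` surrogate is a lumped network, not a transient 3D solution.
- Vorticity accuracy degrades near walls and for strongly curved fields
  (the affine fit is first-order there); refined meshes recover it.
- Phantom meshes are Delaunay triangulations of structured clouds and can
  contain sliver tetrahedra; these carry near-zero volume weight and do
  not affect the weighted means.
- The generator's segmentation ensembles perturb radii and borders only;
  they cannot produce the topology failures (missing branches, fused
  vessels) seen in real challenge data — such members are excluded by the
  caller-supplied exclusion list, mirroring how visually unusable
  surfaces are handled in practice.
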