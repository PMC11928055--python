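# Methods

`memskel` simulates the actin–spectrin membrane skeleton as a
coarse-grained spring-and-cable network coupled to a discrete membrane.
This note records the model, the numerical choices, and the limits of
what the synthetic geometries can show.

## Model

**Nodes and edges.** Short F-actin junctional complexes are point nodes
at positions `r_i` (nm). Spectrin tetramers are Hookean edges between
node pairs with potential `U = (k_s_S/2)(d_j − d0_S)²`: an edge longer
than the 180-nm resting length pulls its nodes together, a shorter one
pushes them apart. Peripheral *linker* nodes (protein complexes that
couple the meshwork to focal adhesions) carry spectrin edges and move
like any mobile node but are excluded from all membrane-force
computations. *Adhesion* nodes are immobile anchors in the extracellular
space; *connector* springs (`k_s_C`, scenario-specific rest length
`d0_C`) tie linkers to anchors and impose extension, compression, shear
or substrate adhesion by starting away from their rest length.

**Spectrin turnover.** A bound edge unbinds when its expansive
(compression-side) force exceeds `F_th = 0.05 pN`, i.e. when
`d_j < d0_S − F_th/k_s_S`. Unbound edges keep their node pair and rebind
as soon as the pair separation is at or above `d0_S`, which guarantees a
reborn edge starts at zero or contractile force. Both checks run every
time step.

**Membrane.** The membrane is discretised by the triangulation of the
initial meshwork restricted to all-actin triangles. Bending energy is

```
E_b = k_b · Σ_(α,β) [1 − cos(θ_αβ − θ0)] · A_α A_β / ⟨A A⟩ ,
```

summed over triangle pairs sharing an edge, with `θ_αβ` the angle
between outward unit normals (`cos θ = n̂_α·n̂_β`; the sign of `sin θ` is
positive when `(n̂_α − n̂_β)·(p_α − p_β) > 0`, which only matters for
`θ0 ≠ 0`; the default spontaneous angle is 0). The area-product weight
is normalised by its mean over the *current* pairs, so small triangle
pairs contribute less. The bending force is the exact negative gradient
of `E_b` — the area weights and the mean normalisation are
differentiated too — so a central finite difference of the energy
reproduces the force to ~1e-7; this is enforced by tests.

Two triangle sets coexist deliberately. The *membrane* triangulation is
fixed for the whole run: a membrane does not disappear when a spectrin
tetramer beneath it detaches, and the fixed set keeps the membrane-force
sample size constant over time. The *myosin* triangulation is rebuilt
from currently bound edges: a cable's triangle dies when one of its
spectrin edges unbinds, which is what triggers cable re-anchoring.

**Surface-area constraint.** On closed geometries the membrane resists
stretching: `E_A = (k_A/2)(A − A0)²/A0` with `A` the area of the full
initial triangulation at current positions and `A0` its value at the
scenario start (the sphere is the permanent reference state). The force
is `−∇E_A`.

**Volume exclusion.** Actin nodes may not enter a hard convex region
obtained by scaling the initial closed surface by `(1 − 0.15)^(1/3)`
about its volumetric centroid (85% of the initial enclosed volume). A
node that steps inside is reset to its pre-step position. Membership is
tested with a Delaunay point-location walk over the scaled hull after an
inscribed/circumscribed-radius prescreen.

**Myosin cables.** Tension-only cables join the centers of two live
triangles; a cable of length `d_k` carries tension `k_c_M · d_k` along
the center-to-center axis (cable potential `(k_c_M/2) d_k²`), and each
end force is split equally among that triangle's three actin nodes.
Cables are removed when shorter than `d_min = 135 nm`; when a support
triangle dies the cable re-anchors to the nearest live triangle within
`d_max = 450 nm` of the lost center, else it is removed. Stochastic
turnover: one addition per step with probability `min(φ_a Δt, 1)`
(uniform over center pairs with separation in `[d_min, d_max]`, by
rejection sampling with a capped number of attempts) and independent
removal of each cable with probability `min(φ_r Δt, 1)`. Runs start with
zero cables. At `φ_a Δt = 2×10⁻⁵`, multi-addition corrections are
negligible.

**Dynamics.** Motion is overdamped: `r ← r + (Δt/ζ)·F_total` with
`ζ = 1.25 pN s/nm` and `Δt = 2 ms`. Each step executes a fixed order —
forces, Euler move, volume exclusion, spectrin unbinding, rebinding,
myosin topology update, stochastic myosin events, recording — so a
(scenario, parameters, seed) triple is bit-reproducible. All randomness
flows from one seeded generator per run. A non-finite force aborts with
a time stamp rather than being clamped.

## Geometries

* **Patch** — a regular offset triangular lattice with every edge
  exactly at `d0_S` (a mechanical rest state of the spectrin subsystem).
  The reference patch is 11 rows × 17 columns: 187 nodes, 506 spectrin
  edges, 320 triangles, 2.88 × 1.56 µm. Isotropic layouts convert all 52
  perimeter nodes to linkers, each anchored 360 nm radially outward and
  10 nm below the plane (initial connector length 360.1389 nm); the
  shear layout converts only the two extreme columns (22 linkers) with
  anchors offset (±360, ±1080, −10) nm (initial length 1138.4638 nm).
* **Sphere** — a Fibonacci point lattice of ~702 vertices at radius
  1.25 µm triangulated by its convex hull and relaxed by tangential
  smoothing: watertight, 2100 edges with median length ≈178 nm. Edge
  lengths are deliberately not rescaled; a sphere of equilateral
  triangles does not exist, so the initial spectrin edges are under
  stress and the shortest ones unbind soon after the start.
* **Adhered cell** — the sphere with all `r_z < 0` nodes projected to
  the substrate plane; every in-plane node is tied to an immobile anchor
  at `(1.1x, 1.1y, −100 nm)`, giving pre-stretched adhesion springs of
  100–160 nm against a 75-nm rest length.

## Scenarios

| name | mesh | connector rest / initial (nm) | duration |
|---|---|---|---|
| ISO_EXTENSION | patch | 270 / 360.1389 | 180 s |
| ISO_COMPRESSION | patch | 450 / 360.1389 | 180 s |
| SHEAR | patch | 270 / 1138.4638 | 120 s + 120 s released |
| SUSPENDED_CELL | sphere | — | 360 s |
| ADHERED_CELL | flattened sphere | 75 / [100, 160] | 360 s |

Release deletes every connector edge and anchor node mid-run; linkers
remain and keep evolving. Rate-ratio sweeps scale the addition rate
`φ_a` only (to rr/5, 5rr, 10rr), keeping the removal clock comparable.

## Observables and statistics

Observables are recorded every 0.5 s: bound-edge count and percentage
attached (denominator fixed at the initial edge count — the convention
that reproduces the printed 75.4420% = 384/509 ratio), cumulative
unbinding/rebinding counters, myosin count, median bound-edge length,
bending energy, and on closed meshes the enclosed volume
(divergence-theorem sum over the full initial triangulation), projected
area (convex hull of the actin (x, y) footprint) and height (actin z
range). Box-plot summaries use linear-interpolation ("type 7")
quartiles; IQR = Q3 − Q1, fences at 1.5 IQR. Myosin lifetimes are
removal minus birth time; cables alive at the end are censored out.
Significance tests are the Wilcoxon signed rank (edge lengths minus
resting length against zero median) and the two-tailed one-sample
t-test, via scipy.

## Numerical choices

* Forward Euler is stable here: the stiffest spring gives
  `2 k Δt/ζ = 0.0064 « 1`; halving `Δt` moves remodeling-free final
  positions by < 0.01 nm RMS.
* The bending sign convention only enters through `cos(θ − θ0)` and the
  default `θ0 = 0`, where the energy is `1 − n̂_α·n̂_β` and no
  singularity exists; for `θ0 ≠ 0` the `sin θ` branch is guarded near
  flat hinges.
* Degenerate (zero-area) triangles raise immediately rather than being
  regularised.
* Hot loops (springs, bending, area constraint) run as numba-compiled
  kernels; the vectorised numpy implementations remain the tested
  reference and a test pins the two paths together to 1e-10.
* Rebinding uses `d ≥ d0_S` rather than exact equality: a discrete-time
  trajectory almost never hits equality, and per-step displacements
  (≤ ~1.4 nm) keep the overshoot, and hence the reborn tension, small.

## What the synthetic geometries do and do not show

The generator's patches are perfectly regular and rest-length-taut, and
the sphere is statistically isotropic; real spectrin meshes are
irregular, polydisperse and pre-stressed. One known consequence is that
under the shear protocol the imposed in-plane principal compression
(~ −20%) drives essentially the whole lattice-edge family aligned with
the compression axis below the 0.05-pN unbinding threshold, so the
simulated patch loses roughly twice as many edges (~284 of 506;
~44% attached at the end) as the published reference run (144 of 509;
75.44%), and myosin cables — which need live triangles — are rare on the
sheared patch. A census with unbinding disabled shows 183/506 edges dip
below threshold even on the intact network, so this is a property of the
loading geometry, not of the remodeling rules; lattice aspect/orientation
sweeps, irregular taut Delaunay meshes, alternative connector plumbing
and remodeling-check cadences all land in the same place. Quantities
that do not hinge on the absolute unbinding count — the recovery of the
median edge length to the resting length after release, the
concentration of unbinding in the first 30 s, the pooled end-state IQRs,
and the whole-cell stabilisation phenomenology — are reproduced at or
near the printed values.

Desk-scale sizes used by the test suite: whole-cell property checks are
single full-length 360-s runs, stochastic shear ensembles use 4–5
replicates (31 in the reference), and `scripts/acceptance.py` uses 10
replicates per ensemble with the full 240-s shear protocol.

## Known limitations

* No ankyrin mid-edge attachment, no spectrin-repeat unfolding, no
  worm-like-chain nonlinearity, no thermal forces, no hydrodynamics.
* The area constraint and volume exclusion are global signals, not
  mechanistic membrane-trafficking or osmotic models.
* Myosin additions are spatially uniform over eligible triangle pairs;
  no force-dependent (catch/slip) myosin kinetics.
* Mesh topology never rewires: unbound edges can only reconnect to
  their original partner.
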