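# memskel

A coarse-grained, seeded simulator of the **actin–spectrin membrane
skeleton**: the spectrin meshwork that underlies the plasma membrane of
red blood cells, neurons and fibroblasts, modelled as a 3D network of
springs and cables coupled to a discrete membrane.

It is written for biophysicists who want to ask mechanism questions that
are hard to reach experimentally: What does membrane bending contribute
to skeletal stability? Why do spectrin unbinding/rebinding and myosin
turnover matter for recovering from imposed stress? What keeps a whole
cell's shape steady despite constant skeletal remodeling?

## Model in brief

* **Spectrin** tetramers are Hookean springs between short-F-actin
  nodes: `F = k_s,S (d_j − d_0,S)` along the edge, with `d_0,S = 180 nm`.
  An edge whose *expansive* (compression-side) force exceeds
  `F^th = 0.05 pN` unbinds; an unbound edge rebinds to its original
  partner once the pair separation returns to `d_0,S`.
* **Membrane bending** on the triangulated meshwork:
  `E_b = k_b Σ [1 − cos(θ_αβ − θ_0)] · A_α A_β / ⟨A A⟩` over adjacent
  triangle pairs (`k_b = 820 pN nm = 200 kT`, `θ_0 = 0`), with the force
  as the exact negative gradient. Closed geometries add a global
  surface-area constraint `E_A = (k_A/2)(A − A_0)²/A_0` and a hard
  cytoplasmic volume-exclusion region (85% of the initial volume).
* **Myosin** is a population of tension-only cables between triangle
  centers (tension `k_c,M · d_k`, equally split over each triangle's
  three actin nodes) with stochastic addition/removal at rates
  `φ_a = 0.01 /s`, `φ_r = 0.0063 /s`, minimum-length removal and
  re-anchoring when a support triangle loses a spectrin edge.
* **Dynamics** are overdamped forward Euler,
  `r ← r + (Δt/ζ) F_total`, `ζ = 1.25 pN s/nm`, `Δt = 2 ms`; runs are
  bit-reproducible for a given seed.

Five scenarios reproduce the canonical in-silico experiments: isotropic
extension and compression of a ~2.5-µm patch, shear with mid-run release
from the adhesions, a suspended spherical cell, and an adhered
(flattened) cell. See `docs/methods.md` for the full model account.

## Worked example

```bash
python examples/shear_release.py
```

builds the reference patch (187 nodes, 506 spectrin edges), shears it
through pre-stretched end connectors for 60 s, releases it and relaxes
60 s more:

```
initial spectrin edges        : 506
unbound by release (t=60 s)   : 165
unbound / rebound at t=120 s  : 299 / 1
percent attached at t=120 s   : 41.11 %
median bound edge length      : 187.232 nm (resting length 180)
```

The compressed-side edges dissociate almost immediately under load
(nearly all removal happens in the first seconds), and after release the
surviving network pulls its median edge length back toward the 180-nm
spectrin resting length while the detached pairs stay clustered. The
other examples show the discrete bending energy and its gradient
(`examples/membrane_forces.py`), stochastic myosin turnover statistics
(`examples/myosin_turnover.py`) and whole-cell shape stabilisation by
the membrane constraints (`examples/whole_cell.py`).

The same experiments are scriptable from the shell:

```bash
memskel simulate --scenario SHEAR --seed 7 --out out/shear
memskel replicates --scenario SHEAR --n 10 --base-seed 1 --out out/reps
memskel mesh --kind sphere --out sphere.vtk
memskel analyze out/reps/observables_seed*.csv
```

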