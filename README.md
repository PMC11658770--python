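# tigon — tension inference and tension–isogonal decomposition for epithelia

During tissue morphogenesis — the canonical example being germ-band
extension in the gastrulating *Drosophila* embryo — epithelial cells
rearrange by T1 transitions: a cell–cell interface collapses and a new,
transverse interface forms between the formerly non-adjacent pair.  The
forces driving this live in the junctional actomyosin cortex and are not
directly measurable, but cortical force balance ties them to geometry:
at every tri-cellular vertex the three tension vectors close into a
**tension triangle** whose internal angles are complementary to the
vertex angles, so *relative* cortical tensions can be read off a
segmented image.  tigon is a Python library for this force-balance
analysis of segmented-and-tracked 2D cell meshes, for physicists and
quantitative biologists working on epithelial mechanics.

What it computes:

* **Local tension inference** — per-vertex tensions
  `T_i ∝ sin(vertex angle between the other two interfaces)` and
  per-interface relative tension `T = T_central / mean(4 flanking
  tensions)` from the kite of the two end-vertex tension triangles, plus
  gridded nematic tension-anisotropy fields.
* **Tension–isogonal decomposition** — force balance pins angles but
  leaves an angle-preserving (*isogonal*) family of deformations free.
  The isogonal tensor `I` solves `l0 · I · T̂_ij = c_i − c_j` (tension
  vectors → centroid differences, least squares over the five kite
  edges), separating active, tension-driven deformation from externally
  imposed strain.  On the interface level, `l = l_ref({T_i}) + Δl_iso`
  with the Voronoi reference length
  `l_ref = l0 (T/2)(cot φ_L + cot φ_R)`.
* **T1 threshold geometry** — setting `l = 0` gives the collapse
  condition; for a symmetric quartet `T_crit(Δl_iso)` solves
  `l0 · T · cot φ = −Δl_iso` with `T = 2 sin(φ/2)`, so
  `T_crit(0) = √2` and a neighbor exchange at 120° angles puts `√3` on
  the emerging interface.
* **T1 detection and classification** — neighbor exchanges and rosettes
  from tracked adjacency changes, exchange-aligned pooling of
  length/tension trajectories, ⟨T_crit⟩ estimation, and active vs
  passive labels from tension-shape vs isogonal-shape dynamics.
* **Minimal quartet model** — positive tension feedback
  `τ_T dT_i/dt = T_i^n − (1/3)Σ T_k^n`, angles slaved to tensions,
  lengths from a cell-shape elastic energy, myosin handover and passive
  tension decay at the exchange; plus a synthetic-data generator that
  emits meshes and tracked sequences with exact ground truth.

## A worked example

```bash
python examples/03_quartet_model.py
```

prints

```
active run:
  exchange at t = 10.02 min, relative tension 1.4138 (threshold sqrt(2))
  post-exchange tension 1.415 -> 1.000 (relaxes toward 1)
passive run:
  exchange at t = 14.97 min at relative tension 1.000 (homeostatic)
  emerging interface starts at 1.7321 (sqrt(3), fixed by geometry) and decays with tau_p
```

The active quartet, started 5% above the uniform fixed point, collapses
when its relative tension reaches the geometric threshold √2 ≈ 1.414 —
nothing in the integrator knows about that number; it emerges from the
elastic relaxation hitting the concyclic tension configuration.  The
passive quartet collapses at constant tension 1, and the geometry of the
flipped tension triangulation fixes √3 ≈ 1.732 on the new interface.
The other scripts in `examples/` cover inference on synthetic meshes
(exact to ~1e-14), the threshold curve, end-to-end event detection and
classification, and the LTC (bridge/cable) order parameter with its
random-Delaunay baseline.

A thin CLI mirrors the library:

```bash
tigon synth --pattern anisotropic --nx 10 --ny 10 --eps 0.25 --out mesh.json
tigon infer --mesh mesh.json --grid 20 --out-dir results/
tigon threshold --l0 4.2 --dliso 0:3:0.05
tigon simulate-quartet --mode active --out traj.csv
```

## Layout

`src/tigon/` — `mesh` (data model, JSON I/O), `labels` (label-image →
mesh), `inference`, `geometry` (triangles, kites, threshold, LTC),
`isogonal`, `t1` (detection/pooling/classification), `quartet` (the
model), `synth` (ground-truth generators), `cli`.  `docs/methods.md`
describes the model, conventions and limitations.
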