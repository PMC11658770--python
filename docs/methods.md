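# Methods

## Force balance and tension inference

tigon represents an epithelium as a planar polygonal cell array with
straight interfaces (coordinates in μm; AP axis = +x, DV axis = +y;
angles in radians internally).  At a tri-cellular vertex in force
balance, the three cortical tension vectors sum to zero and therefore
close into a triangle whose internal angles are the supplements of the
vertex angles.  By the law of sines the tension on interface *i* is
proportional to the sine of the vertex angle between the other two
interfaces; per-vertex tensions are reported normalized to mean 1.
Vertices with any angle ≥ 180°, degree ≠ 3 (transient fourfold/rosette
configurations) or boundary contact are skipped, and every skip is
reported with a reason code.

Per-interface relative tension combines the two end-vertex triangles
(the *kite*).  Each vertex fixes the triangle only up to scale; tigon
matches the two triangles on their shared side (the central-interface
tension) and reports the central tension with the arithmetic mean of the
four flanking tensions normalized to 1.  This is equivalent to the
harmonic mean of the two per-vertex central:mean-flank ratios and is the
unique convention that reproduces `T_central / mean(4 flanks)` exactly
on meshes that are integrable (derived from an actual tension
triangulation); the relative disagreement of the two one-triangle
estimates is kept as a per-interface consistency score (0 on integrable
meshes, > 0 under noise).  Landmarks pinning the convention: uniform
hexagonal lattice → 1, the square threshold configuration
(90°,135°,135° at both ends) → √2, post-exchange equilateral geometry →
√3.

The nematic tension anisotropy at a vertex is the traceless part of
`σ = Σ T_i ê_i⊗ê_i` over unit interface directions — unit, not
full-length, vectors, so tension anisotropy is not conflated with
edge-length anisotropy.  Grid averaging (default 20 μm spacing, grid
anchored at the data bounding box) averages nematic tensors, never
angles; orthogonal nematics cancel.

## Tension–isogonal decomposition

The tension triangulation (one node per cell; edge lengths = tensions;
edges perpendicular to their interfaces) defines a reference cell array
through the Voronoi construction: cell vertices at circumcenters, scaled
by `l0`.  The isogonal tensor `I` is defined by
`l0 · I · T̂_ij = c_i − c_j` with `T̂_ij` the tension vector between the
cells' nodes and `c_i` the area centroids: at a vertex it is solved
exactly from the two independent edge correspondences of the tension
triangle vs the centroid triangle (matched by shared cell identity); for
a quartet it is the unweighted least-squares fit over all five kite
edges, with the residual reported.  The direction of the defining
relation follows the printed formula (tension vectors → centroid
differences); translations are discarded and the residual global
rotation is absorbed into `I` and separated afterwards by polar
decomposition — strain statistics use the symmetric stretch part only.
Because per-vertex tensions carry a mean-1 gauge, `I` is determined up
to a scalar; comparisons against an applied map use the
determinant-normalized (`unimodular`) tensor.

Aspect-ratio conventions (the quantities are dimensionally different, so
two conventions coexist deliberately):

* point sets (cell centroids, tension-triangle corners):
  `sqrt(λ_max/λ_min)` of the second-moment tensor, so stretching points
  ×2 reads 2.0;
* isogonal tensors: `sqrt(σ_max/σ_min)` of the singular values.  This is
  the convention under which the explicit symmetric passive-collapse
  construction — 120° angles maintained, central edge shrunk to zero
  from the hexagonal reference, slant edges at their resting length —
  accumulates exactly `I ∝ diag(1, 1/3)`, aspect √3, the landmark value
  for passive intercalations.

On the interface level, `l = l_ref + Δl_iso` with the signed reference
length `l_ref = l0 (T/2)(cot φ_L + cot φ_R)` (circumcenter separation;
zero exactly at concyclicity, negative past the flip).  The symmetric T1
threshold solves `l0 · T · cot φ = −Δl_iso`, `T = 2 sin(φ/2)`, by
bracketed Brent root-finding on φ ∈ (0, π) to 1e-12; a root exists for
`Δl_iso > −l0`.  `T_crit(0) = √2` analytically.  Note a known tension
between two published numbers: at `Δl_iso ≈ 1.9 μm`, `l0 ≈ 4.2 μm` this
relation yields `T_crit ≈ 1.60`, whereas the measured collapse tension
in wild-type lateral ectoderm is ≈ 1.53; tigon implements the printed
symmetric relation and does not reconcile the difference (the quartet
model below suggests one mechanism: under a *static* pre-stretch the
isogonal length drifts downward during the active collapse, and tigon's
wt-like preset indeed measures ⟨T_crit⟩ ≈ 1.55).

`l0` (default 4.2 μm) converts relative tensions to lengths; the mean
resting interface length (default 3.5 μm) is shipped alongside.  A
calibration helper estimates `l0` from a frame as mean observed interior
length divided by mean dimensionless reference length, which reduces to
`√3 × mean edge length` on a hexagonal lattice; on irregular tissue it
is tigon's own convention, since the two defaults are not related by the
hexagonal formula.

## LTC order parameter

Each tension triangle maps to `(a, b)`: elongation
`a = (√λ₁ − √λ₂)/(√λ₁ + √λ₂)` from the gyration tensor of its corners,
and `b = −cos θ_max`.  Equilateral → (0, −0.5); right isosceles → b = 0;
the (√3,1,1) triangle → b = +0.5.  `b > 0` (obtuse) is classified as a
*bridge* motif, `b < 0` (acute) as a *cable*; the right angle is the
natural separator because the square kite is flip-invariant.  The
disorder baseline is the Delaunay triangulation of uniform random points
(hull-incident triangles excluded, fully seed-determined).  Both
coordinates are invariant under similarity transforms and relabeling.

## Minimal quartet model

A periodic array of identical hexagonal cells with three interface
classes (central + two flanks).  Active tensions obey
`τ_T dT_i/dt = T_i^n − (1/3) Σ_k T_k^n` (default n = 4), conserving
`Σ T_i` (finite myosin pool); integration is fixed-step RK4 with
`dt = 1e-3 τ_T`, and halving `dt` moves the exchange time by < 0.1%.
Angles follow total tensions instantaneously (separation of elastic
scales); lengths minimize
`E_C = λ [Tr(S_C − S_0)]² + µ Tr[(S_C − S_0)²]` at fixed angles.  The
shape tensor is implemented in its subdivision-invariant form
`S_C = Σ l_i ê_i⊗ê_i` (unit directions weighted by length, one term per
interface class) — the only reading linear in interface length, i.e.
unchanged when an interface is subdivided by an extra vertex.  `S_0` is
isotropic by default, calibrated so the uniform-tension hexagon with
edge `l_rest = l0/√3` is the zero-energy state; λ = µ = 1 (only their
ratio matters).  The energy is quadratic in the lengths, so the
constrained minimizer (`l_i ≥ 0`) is obtained by non-negative least
squares — deterministic, no iteration.

A structural consequence worth stating: with an isotropic target shape
the relaxed central length vanishes exactly when the two tension
triangles become concyclic, so the simulator collapses at the geometric
threshold (√2 for symmetric flanks) without that number appearing
anywhere in the code.  For asymmetric flanks the collapse still occurs
at the concyclic configuration, whose *relative* tension
`√(T₁²+T₂²) / mean(T₁,T₂)` exceeds √2 — ensembles with jittered initial
angles therefore average ~1–2% above √2, with the excess carried by
runs whose top two initial tensions nearly tie (they develop strongly
asymmetric flanks before collapsing).

At the exchange: the new total tension is the other diagonal of the
tension parallelogram, `√(2T₁² + 2T₂² − T₀²)` (the periodic quartet's
two triangles are point reflections); the *active* part follows the
myosin handover rule — each cortex carries half an interface's tension
and myosin is continuous across vertices within a cell, so
`T_myo,new = (T₁ + T₂)/2`, provably below the geometric total at the
exchange configuration; the remainder is passive tension decaying as
`exp(−t/τ_p)` while feedback continues on the active tensions (their
conserved sum re-based at the flip).  The single-quartet description is
truncated if a flank later reaches its own force-balance limit (that
would be the next intercalation).  Default timescales: `τ_T = 28 min`
(symmetric runs collapse in ~10–15 min), `τ_p = 2 min` (passive tension
relaxes over minutes); both are configuration values, not constants.

Passive runs disable feedback and contract the DV component of `S_0` at
a prescribed rate (default collapses in ~15 min); driving stops at the
exchange.  Prescribed-isogonal (`hold_dl_iso`) runs adjust `S_0` each
step so the central isogonal length stays at a given value, emulating a
constant external stretch; the threshold-consistency sweep uses this to
compare the simulated flip tension against the analytic `T_crit(Δl_iso)`
through two independent code paths (elastic relaxation + feedback vs
circumcenter geometry + root-finding); agreement is ~0.04%, asserted at
2%.  A `mixed` mode adds an isogonal contraction at `l_rest/24 μm/min`
to the feedback dynamics — the generator's definition of a 50/50 event.

## Synthetic data and what it does (not) show

The generator lays out a tension triangulation (uniform, DV-stretched,
alternating-bridge, cable, or random-Delaunay patterns; bridge/cable are
rows of isosceles triangles with base 1±ε vs legs 1∓ε, ε < 1/3), builds
the cell array at the l0-scaled circumcenters, optionally applies an
isogonal deformation and vertex noise, and emits exact ground truth as a
sidecar (never recomputed).  Two constructions deserve comment:

* *Isogonal fields.*  Applying a raw linear map to vertex positions
  would change angles and is therefore not isogonal.  tigon instead
  keeps every interface direction fixed (hard constraint — angles are
  preserved exactly and inference is provably unaffected) and fits the
  centroids to the mapped generators: on lattice duals this is an exact
  per-edge-class length rescaling; on irregular duals a constrained
  least-squares approximation.
* *Bridge patterns.*  A kite whose apex angles sum past 180° has
  negative reference length — the Voronoi topology is already flipped —
  so strongly obtuse (bridge) triangulations have no zero-isogonal cell
  array; realization raises, and bridge-motif statistics are computed on
  the triangulation itself.  This is not a limitation but the T1
  threshold seen from the other side.

Tracked time series embed quartet-model trajectories in a hexagonal
surround (default frame interval 15 s): all 16 vertices of the four
quartet hexagons follow the model exactly, so inference on the kite
reproduces the model tensions to machine precision, while the surround
stays at rest.  After the exchange the outer quartet corners freeze at
their last pre-flip position (the periodic model has no consistent
embedding into a static surround post-flip); the first post-flip frames
legitimately show a transient fourfold vertex, which event detection
absorbs by matching gained adjacencies up to 4 frames after a loss.
The *snail-like* and *wt-like* presets differ only in a DV isogonal
pre-stretch (0 vs 1.9 μm): the former collapses at the bare √2
threshold, the latter above it.

Synthetic meshes are integrable and (optionally) noisy in vertex
position only.  They do not emulate curved interfaces, segmentation
errors, fold regions, the embryo's curved surface, or non-force-balanced
configurations — passing tests therefore demonstrate correctness of the
geometry and statistics pipeline, not robustness to every real-imaging
artifact.  Boundary-incident vertices, interfaces and cells are excluded
from all statistics; statistics problem sizes in the test suite (8×8 to
20×20 lattices, ensembles of tens of events, 2000-point baselines) are
chosen to make every check exact or tightly bounded while keeping the
suite fast.

## Known limitations

* Tension inference is local and relative; no global variational
  inference, curvature terms, pressures, or absolute calibration.
* The DV component of gridded isogonal fields uses a fixed embryo axis
  (+y), not a locally co-rotating frame.
* The exact conventions behind two published quantities (the `l0`
  calibration from the mean initial length, and the `T_crit ≈ 1.53`
  read-off) are not fully specified by their source; tigon's choices are
  documented above and flagged where they differ.
* Asymmetric-quartet thresholds are computed by the general signed
  reference length, but only the symmetric threshold curve is claimed
  quantitatively.
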