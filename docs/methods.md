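# Methods

`fractalarbor` quantifies how the effective fractal dimension *D* of a
dendritic arbor trades off its potential network connectivity against
the material and metabolic costs of its branches. This note records the
model, the estimators, their numerical conventions, and the choices made
where the design was genuinely open.

## Arbor model

An arbor is a rooted tree of tapered cylindrical segments in continuous
µm coordinates (`CenterlineArbor`). A *branch* is the maximal segment
chain between forks; its length *L* is the sum of its segment lengths,
and the branch level *i* counts forks on the path from the soma
(*i* = 1 for soma-emanating branches). Two angle populations describe
the geometry: *weave angles* θ between consecutive segments along a
branch (median ≈ 12° in CA1 pyramidal-cell reconstructions) and *fork
angles* ϕ, the first weave angle of a branch measured against its
parent's final segment (median ≈ 37°). Angles are computed as
arccos of normalized dot products and always live in [0°, 180°] —
left/right of the local axis is deliberately not distinguished.

Surface models are tube meshes: every segment contributes two rings of
16 vertices and 32 side triangles; terminal segments carry a 14-face fan
cap; a child branch starts from its parent's final ring so tubes stay
connected across forks. Ring frames are parallel-transported along
branches to avoid twist, and the initial in-plane direction is derived
from the arbor's own geometry (first non-collinear segment pair) so the
construction commutes with rigid rotations. The ring arithmetic is
load-bearing: the face-count identities (32 per segment, 14 per cap)
are asserted in the tests.

## Voxelization

Three occupancy conventions coexist, each fit for a different purpose:

* **Conservative surface** (`voxelize`): a voxel is occupied iff a mesh
  triangle intersects its cube (separating-axis test, ties inclusive).
  This is the natural substrate for box counting and for the profile of
  tube models; `fill_interior` adds enclosed voxels via flood fill.
  Box sizes and slide offsets are snapped to whole voxels so a voxel
  never straddles a box boundary.
* **Solid, center-inside** (`solid_voxel_grid`, `model_volume`): a voxel
  counts iff its *center* lies inside the solid (analytic cylinder-union
  test for centerline tubes; axis-parallel parity ray casting for
  generic watertight meshes, with jittered retries at grazing rays).
  Unlike the conservative rule — which overfills a thin tube by roughly
  A·(voxel/2) — this estimator is unbiased, which is what volume ratios
  like V_m/V_b ≈ 1 for a sphere require.
* **Centerline skeleton** (`voxelize_centerline`): zero-width sampling of
  the segment chains, used to estimate scaling exponents where branch
  width is a nuisance parameter (below).

## Box-counting dimension

The sliding box count covers the grid with cubic boxes of side L_box,
slides the partition diagonally in fixed steps (0.25 µm at the default
4 voxels/µm), and keeps the minimum occupied count; N_box ~ L_box^−D.
The number of offsets per size is capped (64 by default) by even
thinning. The dimension is fitted in log-log space: within the
admissible window — from a fine cutoff up to one fifth of the longest
bounding-box side (fewer than five boxes per side forces every box to
fill and the slope drifts to 3) — every contiguous point range spanning
at least one decade is fitted and the best-R² fit wins, ties going to
the wider range. A window narrower than one decade is a hard error, not
a silent degradation.

The fine cutoff matters more than it looks:

* For width-carrying tube models it is 2 µm, below which boxes probe the
  2-D tube surface (slope → 2). But the width correction decays slowly
  above the cutoff: a 12-level width-1 µm tree built with scaling
  exponent 1.4 *measures* ≈ 1.66 through its tube mesh — the fattening
  contributes ~+0.25 across the 2–8 µm octaves.
* The package therefore estimates the scaling exponent of generated
  trees from the **centerline skeleton**, where the recovered D tracks
  the construction exponent to within 0.1 for targets 1.2–1.6. The fine
  cutoff is then the shortest branch length, clipped between two voxels
  and 2 µm. Without that clip the best-R² search happily locks onto the
  *exact* slope-1 power law of the sub-branch straight-line regime —
  a perfectly straight line is also a perfect fit.

## Connectivity profile

The profile P from a view direction is the area of the arbor's
orthographic shadow on a 1 µm² lattice: occupied voxel centers are
rotated so the view direction becomes the projection axis (minimal
rotation; fixed 180° about x at the antipode), shifted to the rotated
centroid, rounded half-up, and counted once per cell. Counting
duplicates once is the point: branches hiding behind one another expose
no additional synapses. Before projection the arbor is uniformly
dilated by the spine reach (2 µm), implemented sparsely as a union of
lattice balls; a density pre-factor below 1 can be applied to P directly
when a lower spine density is wanted. Because the dilated layer is in P
but not in the membrane area A_s, P/A_s may exceed 1.

Round-and-count overestimates a *convex* body's shadow by ~0.35 µm of
silhouette growth (+6% for an r = 10 µm sphere), which is invisible for
arbors but not for the Euclidean reference values. When the grid is
finer than the 1 µm cell, `project_area` therefore counts a cell only
when its *center* is hit (the two rules coincide at 1 voxel/µm). The
sphere reference value P/A_b is computed this way at 4 voxels/µm and
lands at 0.258 against the analytic 1/4 — the residual is the staircase
shadow of the voxelized ball, shrinking with resolution.

Orientation averages use a Fibonacci (golden-angle) lattice of
viewpoints. 201 directions agree with 10,001 to well under 1% on
weaving-tree fixtures; 10,001 are used for profile-sphere maps.

## Cost metrics

* **A_s** — membrane area: each mesh face is split into four midpoint
  sub-triangles (exactly area-preserving) and a sub-face is discarded
  when all three of its vertices lie strictly inside another segment's
  open cylinder (axis distance < r and axial coordinate in (0, l); ties
  count as outside). Terminal end caps are included. The containment
  test runs segment→points through one KD-tree over the unique
  subdivision vertices.
* **A_b, V_b** — area and volume of the convex hull of the mesh
  vertices (`scipy.spatial.ConvexHull`); coplanar inputs are flagged
  degenerate with zero volume rather than erroring.
* **V_m** — branch volume as the voxel-center union of the segment
  cylinders, so overlapping segments count once.

## Synthetic study inputs

* **H-trees**: binary trees with level lengths L_i = L_1 / 2^((i−1)/D),
  12 levels and 1 µm width by default, siblings forking at ±90° to the
  parent axis, the branching plane rotating 90° about the parent axis
  per level in 3D. When the total wire length is prescribed, L_1 is
  solved so the sum over 2^(i−1) branches per level matches it exactly,
  keeping total length constant across D. The log N vs log(L/L_max)
  branch histogram then has slope −D identically.
* **Weaving H-trees** subdivide each branch (default granularity = the
  branch width) and bend it with angles drawn from a fractional
  Gaussian noise sequence (Davies–Harte circulant embedding), rescaled
  to the requested standard deviation; azimuths are uniform. The Hurst
  exponent defaults to 0.75 — any value in (0,1) gives a self-similar
  weave; the default is a documented choice, not a measurement. Bending
  preserves arc length to 1e-6 relative.
* **Equal-length trees** set every branch to a common length and the
  fork angle to a prescribed ϕ. Here the classic 90° plane rotation
  degenerates: equal-length branches retrace a cubic lattice exactly and
  thousands of branches collapse onto a handful of grid lines. The
  equal-length generator therefore advances the branching plane by the
  golden angle per level, keeping branches spread through the volume.
* **Toy arbors** emulate basal/apical dendrites statistically:
  log-normal segment lengths and widths, half-normal weave/fork angles
  in uniformly random azimuthal planes, forking to a set level count.
  Only the medians (θ 12°, ϕ 37°, segment 2.4 µm, width 1.4 µm) are
  anchored; the joint distribution of real reconstructions — branch
  correlations, taper, self-avoidance, laminar orientation — is *not*
  reproduced. Passing tests on toys validate the machinery, not any
  claim about real CA1 statistics; those require the deposited
  reconstructions (`neuron_population_check`).
* **Euclidean fixtures**: icosphere (D = 3 reference), cube, straight
  line (D = 1).

All generators are pure functions of (spec, seed).

## Angle manipulation

Multiplying the weave and/or fork angles by α ∈ [0, 2] produces arbor
variants spanning D beyond natural values. Junctions are processed from
the angles furthest from the soma inwards; each junction's downstream
subtree is rigidly rotated in the plane of the two defining vectors so
the angle becomes α·θ. Because outer junctions act strictly downstream,
every junction still sees its original pivot, axis, and angle when its
turn comes — the net map of a node is the composition of its ancestor
junctions' original-frame rotations, which the implementation evaluates
in one pass with an accumulated affine transform per node. Scaled
angles above 180° fold back (360° − α·θ; a 100° fork at α = 2 measures
160°), and folded counts are reported. Junctions at 0° or 180° have no
rotation plane and are fixed points. Self-intersections after scaling
are tolerated (they are rare below α = 2) and countable via exact
segment-segment distances. With simultaneous θ and ϕ scaling, both
angle kinds are handled in the same inward sweep.

## Optimization statistics

Per arbor variant the pipeline records D, P, A_s, A_b, V_b, V_m. Across
an ensemble, the connectivity density P/A_b, operating cost A_s/A_b and
building cost V_m/V_b are fitted with 3rd-degree polynomials of D
(binned averages are computed alongside for display), and the
optimization indicators are the derivative ratios
R_PA = (P/A_b)′ / (A_s/A_b)′ and R_PV = (P/A_b)′ / (V_m/V_b)′,
evaluated analytically on a 0.001-wide D grid over the data range.
Points where the denominator derivative vanishes are masked. Peaks are
located by grid argmax with 3-point quadratic refinement; a maximum on
the range boundary is flagged as "no interior peak" rather than
reported as a peak. Fits are never pooled across H-trees and
neuron-like arbors. Raw records, not binned averages, feed the fits.

## Study conditions and problem sizes

The H-tree ensemble used by the reproduction script holds total wire
length fixed at 4000 µm across 12-level trees with scaling exponents
linspace(1.1, 1.9, 7), straight plus four weave widths
σ ∈ {10°, 20°, 30°, 40°}, 201 viewpoints, box counting of the
centerline at 4 voxels/µm, V_m at 2 voxels/µm — 35 arbors in a few
minutes on one core. The equal-length ϕ = 90° tree uses 12 levels and
branch length 9 µm, the densest configuration whose admissible box-size
window still spans one decade.

Two honest limitations surfaced by this pipeline are worth stating
plainly. First, a 10–12-level equal-length tree of width 1 µm cannot
reach D = 3 under the fit rule itself: one decade of admissible window
forces a ≥100 µm bounding box, space-filling at 2 µm boxes then needs
roughly S³/9 ≈ 10⁵ µm of wire, but 4095 branches of the required length
spread far beyond 100 µm. Tree depth, not the construction, is the
limit: at 12 levels the measured D saturates near 2.2. Second,
on this ensemble R_PA decreases monotonically over the measured D
range, so its maximum sits at the low-D boundary rather than at an
interior peak; R_PV does peak in the interior, at D ≈ 1.35. R_PA < 1
and R_PV > 1 hold throughout the natural-D region.

## Numerical conventions

* Voxel grids anchor at the bounding-box minimum corner; voxel (0,0,0)
  covers [0, side)³ (half-open). Duplicate centerline samples
  (zero-length segments) are merged with a warning, not errors.
* Box sizes are snapped to whole voxels and deduplicated; slide steps
  are at least one voxel.
* Projection rounding is half-up with a 1e-9 tie epsilon — numpy's
  half-to-even would merge adjacent columns of exactly-half-integer
  lattices (axis-aligned views of voxel centers).
* fGn synthesis clips numerically negative circulant eigenvalues; the
  sequence is rescaled to the requested sample standard deviation, so
  only the correlation structure of the embedding matters.
* Seeds: every stochastic generator takes an explicit integer seed;
  derived streams use `numpy` SeedSequence spawning with fixed salts.
* Grid-based quantities (V_m, P, D) are only statistically invariant
  under rotation; exact invariants (lengths, angles, hull metrics,
  A_s) are tested at 1e-6 relative, grid quantities at 5–10%.
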