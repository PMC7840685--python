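"""Branch-level statistics and cost-side geometric metrics.

The branch level ``i`` counts forks on the path from the soma (i = 1 for
branches emerging from the soma).  Weave angles θ are the angles between
consecutive segments along a branch; the fork angle ϕ of a branch is its
first weave angle, measured against the parent branch's final segment —
branches emanating directly from the soma carry no ϕ.  All angles are
measured via arccos of normalized dot products and therefore live in
[0°, 180°]: left/right of the local axis is not distinguished.

Cost metrics:

* ``A_s`` — membrane surface area of the tube mesh, with each face split
  into four midpoint sub-triangles and sub-faces discarded when all three
  vertices lie strictly inside another segment's cylinder (operating-cost
  proxy; endcap faces at terminals are included).
* ``A_b``/``V_b`` — area and volume of the convex hull of the mesh
  vertices (the bounding surface/volume).
* ``V_m`` — volume of the branch tubes as a union (building-cost proxy),
  estimated by counting voxels whose center falls inside the solid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from . import _geom
from .arbor import CenterlineArbor, TriangleMesh, VoxelGrid
from .errors import DegenerateGeometryError, ParameterError, StructureError

__all__ = [
    "AngleSet",
    "BranchStats",
    "CostMetrics",
    "HullMetrics",
    "assign_levels",
    "branch_length_stats",
    "measure_angles",
    "equalize_branch_lengths",
    "surface_area",
    "hull_metrics",
    "model_volume",
]


@dataclass
class AngleSet:
    """Measured weave and fork angles with their rotation-plane normals.

    ``weave`` rows: (branch_id, junction_index, angle_deg, nx, ny, nz);
    ``fork`` rows: (branch_id, angle_deg, nx, ny, nz).  The normal is the
    unit cross product of the two defining directions (zero when they are
    collinear and the plane is undefined).
    """

    weave_branch: np.ndarray
    weave_index: np.ndarray
    weave_deg: np.ndarray
    weave_normal: np.ndarray
    fork_branch: np.ndarray
    fork_deg: np.ndarray
    fork_normal: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        return self.weave_deg

    @property
    def phi(self) -> np.ndarray:
        return self.fork_deg


@dataclass
class BranchStats:
    lengths: np.ndarray          #: per-branch L (µm)
    levels: np.ndarray           #: per-branch level i
    L_max: float
    rel_lengths: np.ndarray      #: L / L_max
    hist_centers: np.ndarray     #: representative L/L_max per histogram bin
    hist_counts: np.ndarray      #: branch count N per bin
    loglog_slope: float | None   #: OLS slope of log N vs log(L/L_max); None if undefined


@dataclass
class CostMetrics:
    A_s: float
    A_b: float
    V_b: float
    V_m: float


@dataclass
class HullMetrics:
    area: float
    volume: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Branch levels and length statistics
# ---------------------------------------------------------------------------

def assign_levels(arbor: CenterlineArbor) -> CenterlineArbor:
    """Assign ``Branch.level`` in place: 1 + forks on the path from the soma."""
    for b in arbor.branches:
        level = 1
        p = b.parent_branch
        while p is not None:
            level += 1
            p = arbor.branches[p].parent_branch
        b.level = level
    return arbor


def branch_length_stats(arbor: CenterlineArbor, n_bins: int = 10) -> BranchStats:
    """Histogram of branch count N versus L/L_max and its log-log slope.

    When there are no more distinct lengths than bins (H-trees), each
    distinct length forms its own bin, so the analytic slope -D of a
    straight H-tree is recovered exactly.  A single occupied bin leaves
    the slope undefined (``None``).
    """
    assign_levels(arbor)
    lengths = np.array([b.length for b in arbor.branches])
    levels = np.array([b.level for b in arbor.branches])
    L_max = float(lengths.max())
    rel = lengths / L_max

    distinct = np.unique(np.round(rel, 9))
    if len(distinct) <= max(n_bins, 16):
        centers = distinct
        counts = np.array([np.sum(np.isclose(rel, c, rtol=1e-8)) for c in distinct])
    else:
        edges = np.geomspace(rel.min() * (1 - 1e-9), 1.0 + 1e-9, n_bins + 1)
        counts, _ = np.histogram(rel, bins=edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        keep = counts >= 1
        counts, centers = counts[keep], centers[keep]

    if len(centers) < 2:
        slope = None
    else:
        x = np.log10(centers)
        y = np.log10(counts.astype(float))
        slope = float(np.polyfit(x, y, 1)[0])
    return BranchStats(lengths, levels, L_max, rel, centers, counts, slope)


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def _angle_between(u: np.ndarray, v: np.ndarray) -> tuple[float, np.ndarray]:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    ang = float(np.degrees(np.arccos(c)))
    n = np.cross(u, v)
    nn = np.linalg.norm(n)
    normal = n / nn if nn > 1e-12 else np.zeros(3)
    return ang, normal


def measure_angles(arbor: CenterlineArbor) -> AngleSet:
    """Measure all weave angles θ and fork angles ϕ of an arbor."""
    wb, wi, wd, wn = [], [], [], []
    fb, fd, fn = [], [], []
    branches = arbor.branches
    for b in branches:
        dirs = [s.direction for s in b.segments]
        for j in range(len(dirs) - 1):
            ang, nrm = _angle_between(dirs[j], dirs[j + 1])
            wb.append(b.branch_id)
            wi.append(j)
            wd.append(ang)
            wn.append(nrm)
        if b.parent_branch is not None:
            parent_dir = branches[b.parent_branch].segments[-1].direction
            ang, nrm = _angle_between(parent_dir, dirs[0])
            fb.append(b.branch_id)
            fd.append(ang)
            fn.append(nrm)
    return AngleSet(
        np.array(wb, dtype=np.int64),
        np.array(wi, dtype=np.int64),
        np.array(wd, dtype=float),
        np.array(wn, dtype=float).reshape(-1, 3),
        np.array(fb, dtype=np.int64),
        np.array(fd, dtype=float),
        np.array(fn, dtype=float).reshape(-1, 3),
    )


# ---------------------------------------------------------------------------
# Branch-length equalization
# ---------------------------------------------------------------------------

def equalize_branch_lengths(arbor: CenterlineArbor, preserve_total: bool = True,
                            common_length: float | None = None) -> CenterlineArbor:
    """Rescale every branch to a common length, keeping its weave shape.

    Each branch's segment chain is scaled uniformly along its own
    directions, so weave and fork angles are untouched; downstream
    subtrees are re-anchored at the displaced branch tips.  With
    ``preserve_total`` the common length is total/branch-count so the
    combined wire length matches the input arbor exactly.
    """
    branches = arbor.branches
    if not branches:
        raise StructureError("arbor has no branches")
    if common_length is None:
        if not preserve_total:
            raise ParameterError("need preserve_total=True or an explicit common_length")
        common_length = arbor.total_length / len(branches)

    from .arbor import CenterlineNode

    new_pos: dict[int, np.ndarray] = {}
    for sid in arbor.soma_ids:
        new_pos[sid] = arbor.nodes[sid].position.copy()
    for rid in arbor.root_ids:
        new_pos.setdefault(rid, arbor.nodes[rid].position.copy())

    # process branches in creation order: parents precede children
    for b in branches:
        scale = common_length / b.length
        anchor_old = b.node_ids[0]
        start = new_pos.get(anchor_old, arbor.nodes[anchor_old].position)
        pos = start.copy()
        for nid_prev, nid, seg in zip(b.node_ids[:-1], b.node_ids[1:], b.segments):
            pos = pos + seg.direction * (seg.length * scale)
            new_pos[nid] = pos.copy()

    nodes = [
        CenterlineNode(n.id, new_pos.get(n.id, n.position), n.radius, n.parent_id, n.kind)
        for n in arbor.nodes.values()
    ]
    return CenterlineArbor(nodes)


# ---------------------------------------------------------------------------
# Surface area with interior-face exclusion
# ---------------------------------------------------------------------------

def surface_area(mesh: TriangleMesh, arbor: CenterlineArbor | None = None,
                 tol: float = 1e-9) -> float:
    """Model surface area A_s (µm²) with midpoint subdivision and
    exclusion of faces buried inside other segments.

    Every face is split into 4 midpoint sub-triangles (area preserving);
    a sub-face contributes nothing when all three of its vertices lie
    strictly inside some *other* segment's finite cylinder (axis distance
    < radius and axial coordinate in (0, length); boundary ties count as
    outside).  Without a face→segment mapping the raw mesh area is
    returned with a warning.
    """
    if mesh.segment_of_face is None or arbor is None:
        if arbor is not None or mesh.segment_of_face is not None:
            warnings.warn("missing segment mapping or arbor; returning raw mesh area")
        return mesh.area()

    V = mesh.vertices
    F = mesh.faces
    n_v = len(V)
    # unique edges → shared midpoint ids (midpoint of edge e gets id n_v + e)
    raw_edges = np.concatenate(
        [F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]], axis=0
    )
    raw_edges.sort(axis=1)
    edges, edge_of = np.unique(raw_edges, axis=0, return_inverse=True)
    e01, e12, e20 = np.split(edge_of, 3)
    P = np.concatenate([V, 0.5 * (V[edges[:, 0]] + V[edges[:, 1]])], axis=0)

    # sub-triangle point ids: (F, 4, 3)
    sub_ids = np.empty((len(F), 4, 3), dtype=np.int64)
    sub_ids[:, 0] = np.stack([F[:, 0], n_v + e01, n_v + e20], axis=1)
    sub_ids[:, 1] = np.stack([n_v + e01, F[:, 1], n_v + e12], axis=1)
    sub_ids[:, 2] = np.stack([n_v + e20, n_v + e12, F[:, 2]], axis=1)
    sub_ids[:, 3] = np.stack([n_v + e01, n_v + e12, n_v + e20], axis=1)

    count_in, sole_seg = _segment_containment(P, arbor, tol)
    # point buried w.r.t. owner o: inside >=2 segments, or inside exactly one != o
    owner = mesh.segment_of_face  # (F,)
    cnt = count_in[sub_ids]                       # (F, 4, 3)
    sole = sole_seg[sub_ids]
    pt_buried = (cnt >= 2) | ((cnt == 1) & (sole != owner[:, None, None]))
    buried = pt_buried.all(axis=2)                # (F, 4)

    tri = P[sub_ids]                              # (F, 4, 3, 3)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[..., 1, :] - tri[..., 0, :], tri[..., 2, :] - tri[..., 0, :]),
        axis=-1,
    )
    return float(areas[~buried].sum())


def _segment_containment(P: np.ndarray, arbor: CenterlineArbor, tol: float):
    """Per point: number of segments whose open cylinder strictly contains
    it, and (when exactly one does) that segment's index.

    Candidates are gathered segment→points from one KD-tree over all the
    points, querying balls around samples along each segment's axis.
    """
    starts, ends, radii = arbor.segment_arrays()
    axes = ends - starts
    lens = np.linalg.norm(axes, axis=1)
    dirs = axes / lens[:, None]

    spacing = np.maximum(radii, 1e-6)
    n_samp = np.maximum(np.ceil(lens / spacing).astype(np.int64) + 1, 2)
    samp_owner, k = _geom.expand_ranges(np.zeros(len(lens), dtype=np.int64), n_samp)
    t = k / (n_samp[samp_owner] - 1)
    samples = starts[samp_owner] + axes[samp_owner] * t[:, None]
    # a point inside the cylinder is within sqrt(r² + (gap/2)²) of some sample
    ball_r = np.sqrt(radii**2 + (spacing * 0.5) ** 2)[samp_owner] + 1e-9
    if np.ptp(ball_r) < 1e-12:
        ball_r = float(ball_r[0])

    tree = cKDTree(P)
    neighbors = tree.query_ball_point(samples, ball_r, return_sorted=False)
    counts = np.fromiter((len(nb) for nb in neighbors), dtype=np.int64,
                         count=len(neighbors))
    n_pts = len(P)
    count_in = np.zeros(n_pts, dtype=np.int64)
    sole_seg = np.full(n_pts, -1, dtype=np.int64)
    if counts.sum() == 0:
        return count_in, sole_seg
    flat = np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neighbors if nb])
    seg_idx = np.repeat(samp_owner, counts)

    # exact open-cylinder test on the (duplicated) pair list
    rel = P[flat] - starts[seg_idx]
    ax = np.einsum("ij,ij->i", rel, dirs[seg_idx])
    ok = (ax > tol) & (ax < lens[seg_idx] - tol)
    d2 = np.einsum("ij,ij->i", rel, rel) - ax**2
    ok &= d2 < (radii[seg_idx] - tol) ** 2
    # deduplicate only the few inside-pairs (overlapping sample balls)
    key = flat[ok] * np.int64(len(lens)) + seg_idx[ok]
    key = np.unique(key)
    pt_in = key // len(lens)
    seg_in = key % len(lens)
    np.add.at(count_in, pt_in, 1)
    sole_seg[pt_in] = seg_in  # valid wherever count_in == 1
    return count_in, sole_seg


# ---------------------------------------------------------------------------
# Convex hull and model volume
# ---------------------------------------------------------------------------

def hull_metrics(points: np.ndarray) -> HullMetrics:
    """Convex-hull facet area A_b and enclosed volume V_b of a point set."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ParameterError("need at least 4 points for a 3-D hull")
    try:
        hull = ConvexHull(points)
    except QhullError:
        # coplanar/collinear: report the planar hull area, zero volume
        try:
            hull2 = ConvexHull(points[:, _spanning_axes(points)])
            return HullMetrics(float(2 * hull2.volume), 0.0, degenerate=True)
        except (QhullError, ValueError):
            return HullMetrics(0.0, 0.0, degenerate=True)
    return HullMetrics(float(hull.area), float(hull.volume), degenerate=False)


def _spanning_axes(points: np.ndarray) -> list[int]:
    spans = points.max(axis=0) - points.min(axis=0)
    return list(np.argsort(spans)[-2:])


def model_volume(mesh: TriangleMesh, resolution: float = 4.0,
                 arbor: CenterlineArbor | None = None) -> float:
    """Branch volume V_m (µm³): voxel centers inside the solid, counted once.

    For centerline tube models the containment test is the analytic union
    of segment cylinders (overlaps counted once).  For generic watertight
    meshes containment is decided by axis-parallel parity ray casting; an
    open (leaking) surface raises an error naming the defect.  Counting
    voxel centers makes the estimator unbiased for thin tubes, unlike the
    conservative any-intersection rule which overfills by ~A·voxel/2.
    """
    grid = solid_voxel_grid(mesh, resolution, arbor=arbor)
    return grid.n_occupied * grid.voxel_side**3


def solid_voxel_grid(mesh: TriangleMesh, resolution: float = 4.0,
                     arbor: CenterlineArbor | None = None) -> VoxelGrid:
    """Occupancy grid of voxels whose *center* lies inside the solid model."""
    if resolution <= 0:
        raise ParameterError("resolution must be > 0")
    if arbor is not None:
        origin, coords = _solid_coords_from_cylinders(arbor, resolution)
    else:
        origin, coords = _solid_coords_parity(mesh, resolution)
    return VoxelGrid(resolution, origin, coords)


def _solid_coords_from_cylinders(arbor: CenterlineArbor, resolution: float):
    starts, ends, radii = arbor.segment_arrays()
    lo = np.minimum(starts, ends).min(axis=0) - radii.max()
    side = 1.0 / resolution
    occupied: list[np.ndarray] = []
    for s, e, r in zip(starts, ends, radii):
        bmin = np.minimum(s, e) - r
        bmax = np.maximum(s, e) + r
        ilo = np.floor((bmin - lo) * resolution).astype(np.int64)
        ihi = np.ceil((bmax - lo) * resolution).astype(np.int64)
        axes = [np.arange(ilo[k], ihi[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + 0.5
        p = lo + centers * side
        d = e - s
        L = np.linalg.norm(d)
        u = d / L
        rel = p - s
        ax = rel @ u
        ok_axial = (ax >= 0) & (ax <= L)
        perp2 = np.einsum("ij,ij->i", rel, rel) - ax**2
        ok = ok_axial & (perp2 <= r * r)
        occupied.append((centers[ok] - 0.5).astype(np.int64))
    coords = np.concatenate(occupied, axis=0)
    if len(coords) == 0:
        return lo, coords.reshape(0, 3)
    shift = coords.min(axis=0)
    return lo + shift * side, _geom.unique_rows(coords - shift)


def _solid_coords_parity(mesh: TriangleMesh, resolution: float):
    """Voxel centers inside a watertight mesh via z-ray parity."""
    lo, hi = mesh.bounds()
    side = 1.0 / resolution
    nx, ny = (np.ceil((hi[:2] - lo[:2]) * resolution).astype(int))
    tri = mesh.vertices[mesh.faces]

    # bin triangles by the xy cells their projection covers
    t2 = (tri[:, :, :2] - lo[:2]) * resolution
    tlo = np.clip(np.floor(t2.min(axis=1)).astype(np.int64), 0, [nx - 1, ny - 1])
    thi = np.clip(np.floor(t2.max(axis=1)).astype(np.int64) + 1, 1, [nx, ny])

    out_coords: list[np.ndarray] = []
    z0 = lo[2]
    nz = int(np.ceil((hi[2] - z0) * resolution))
    cell_of_tri: dict[tuple[int, int], list[int]] = {}
    for t in range(len(tri)):
        for cx in range(tlo[t, 0], thi[t, 0]):
            for cy in range(tlo[t, 1], thi[t, 1]):
                cell_of_tri.setdefault((cx, cy), []).append(t)

    for (cx, cy), tids in cell_of_tri.items():
        px = lo[0] + (cx + 0.5) * side
        py = lo[1] + (cy + 0.5) * side
        zs = _ray_z_crossings(tri[tids], px, py)
        if zs is None:
            # grazing hit on an edge/vertex: retry with a jittered ray
            for jx, jy in ((0.137, 0.261), (-0.177, 0.313), (0.291, -0.123)):
                zs = _ray_z_crossings(tri[tids], px + jx * side, py + jy * side)
                if zs is not None:
                    break
        if zs is None:
            raise DegenerateGeometryError(
                "open mesh: z-ray parity failed (odd crossing count)"
            )
        if len(zs) == 0:
            continue
        centers_z = z0 + (np.arange(nz) + 0.5) * side
        inside = np.zeros(nz, dtype=bool)
        for zin, zout in zip(zs[0::2], zs[1::2]):
            inside |= (centers_z > zin) & (centers_z < zout)
        zi = np.flatnonzero(inside)
        if len(zi):
            col = np.empty((len(zi), 3), dtype=np.int64)
            col[:, 0] = cx
            col[:, 1] = cy
            col[:, 2] = zi
            out_coords.append(col)
    if not out_coords:
        return lo, np.empty((0, 3), dtype=np.int64)
    return lo, np.concatenate(out_coords, axis=0)


def _ray_z_crossings(tris: np.ndarray, px: float, py: float) -> np.ndarray | None:
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    d = np.array([px, py])
    v0 = b[:, :2] - a[:, :2]
    v1 = c[:, :2] - a[:, :2]
    v2 = d - a[:, :2]
    den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (v2[:, 0] * v1[:, 1] - v2[:, 1] * v1[:, 0]) / den
        v = (v0[:, 0] * v2[:, 1] - v0[:, 1] * v2[:, 0]) / den
        hit = (np.abs(den) > 1e-15) & (u >= 0) & (v >= 0) & (u + v <= 1)
    if not hit.any():
        return np.empty(0)
    z = a[hit, 2] + u[hit] * (b[hit, 2] - a[hit, 2]) + v[hit] * (c[hit, 2] - a[hit, 2])
    z = np.sort(z)
    # merge duplicate crossings at shared edges (within tolerance)
    keep = np.concatenate(([True], np.diff(z) > 1e-9))
    z = z[keep]
    if len(z) % 2 != 0:
        return None
    return z


def cost_metrics(mesh: TriangleMesh, arbor: CenterlineArbor | None = None,
                 vm_resolution: float = 4.0) -> CostMetrics:
    """Convenience bundle: A_s, A_b, V_b, V_m for one arbor model."""
    hm = hull_metrics(mesh.vertices)
    if hm.degenerate:
        raise DegenerateGeometryError("arbor hull is degenerate (coplanar)")
    A_s = surface_area(mesh, arbor)
    V_m = model_volume(mesh, vm_resolution, arbor=arbor)
    return CostMetrics(A_s=A_s, A_b=hm.area, V_b=hm.volume, V_m=V_m)
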