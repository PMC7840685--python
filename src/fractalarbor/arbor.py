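"""Arbor data model, SWC / Wavefront-OBJ I/O, mesh synthesis and voxelization.

A dendritic arbor is represented as a rooted tree of tapered cylindrical
segments (``CenterlineArbor``).  Branches are the maximal segment chains
between forks; the branch length ``L`` is the sum of its segment lengths.
Surface models are triangle meshes built from rings of 16 vertices per
segment end (32 side faces per segment, 14-face end caps at terminals),
mirroring how tracing software exports tube models of dendrites.

Coordinates are continuous µm.  Voxel grids are axis-aligned occupancy
grids anchored at the bounding-box minimum corner; voxel ``(0,0,0)``
covers ``[0, side)^3`` from the origin (half-open convention).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import trimesh as _trimesh

from . import _geom
from .errors import (
    MeshFormatError,
    ParameterError,
    StructureError,
    SWCFormatError,
)

SOMA = "soma"
DENDRITE = "dendrite"

_SWC_TYPE_SOMA = 1
_SWC_TYPE_DENDRITE = 3

RING_POINTS = 16  #: vertices per cross-section ring
CAP_FACES = RING_POINTS - 2  #: triangles in a terminal end cap (fan of a 16-gon)


@dataclass
class CenterlineNode:
    """One centerline sample: position (µm), radius (µm, = W/2), topology."""

    id: int
    position: np.ndarray
    radius: float
    parent_id: int | None
    kind: str = DENDRITE

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ParameterError("node position must be a 3-vector")
        if self.kind == DENDRITE and not self.radius > 0:
            raise ParameterError(f"dendrite node {self.id} needs radius > 0")


@dataclass
class Segment:
    """A straight tapered-cylinder piece of a branch."""

    start: np.ndarray
    end: np.ndarray
    radius: float
    branch_id: int

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        return _geom.unit(self.end - self.start)


@dataclass
class Branch:
    """Maximal chain of segments between forks (or soma / terminal)."""

    segments: list[Segment]
    level: int | None = None
    branch_id: int = -1
    node_ids: list[int] = field(default_factory=list)
    parent_branch: int | None = None  #: branch id of the parent, None if soma-emanating

    @property
    def length(self) -> float:
        return float(sum(s.length for s in self.segments))


class CenterlineArbor:
    """Rooted tree of centerline nodes with derived branch structure.

    Parameters
    ----------
    nodes
        Iterable of :class:`CenterlineNode`.  Node ids must be unique and
        every non-root node must name an existing parent.  Consecutive
        duplicate positions (zero-length segments, a common tracing
        artifact) are merged silently.
    """

    def __init__(self, nodes: Iterable[CenterlineNode]):
        self.nodes: dict[int, CenterlineNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise StructureError(f"duplicate node id {n.id}")
            self.nodes[n.id] = n
        if not self.nodes:
            raise StructureError("arbor has no nodes")
        self._validate_tree()
        self._drop_zero_length()
        self._branches: list[Branch] | None = None

    # -- topology ---------------------------------------------------------
    def _validate_tree(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if not roots:
            raise StructureError("arbor has no root (cycle?)")
        self.children: dict[int, list[int]] = {i: [] for i in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is None:
                continue
            if n.parent_id not in self.nodes:
                raise StructureError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
            self.children[n.parent_id].append(n.id)
        # connectivity + acyclicity via BFS from roots
        seen: set[int] = set()
        stack = [r.id for r in roots]
        while stack:
            i = stack.pop()
            if i in seen:
                raise StructureError("cycle detected in arbor topology")
            seen.add(i)
            stack.extend(self.children[i])
        if len(seen) != len(self.nodes):
            raise StructureError("arbor is disconnected")
        self.root_ids = [r.id for r in roots]

    def _drop_zero_length(self) -> None:
        """Merge nodes that coincide with their parent (< 1e-9 µm apart)."""
        removed = {}
        for n in list(self.nodes.values()):
            if n.parent_id is None:
                continue
            p = self.nodes[n.parent_id]
            if np.linalg.norm(n.position - p.position) < 1e-9:
                removed[n.id] = n.parent_id
        if not removed:
            return
        warnings.warn(f"dropped {len(removed)} zero-length segments")

        def resolve(i: int) -> int:
            while i in removed:
                i = removed[i]
            return i

        for i in removed:
            del self.nodes[i]
        for n in self.nodes.values():
            if n.parent_id is not None:
                n.parent_id = resolve(n.parent_id)
        self._validate_tree()

    # -- derived structure ------------------------------------------------
    @property
    def soma_ids(self) -> list[int]:
        return [i for i, n in self.nodes.items() if n.kind == SOMA]

    @property
    def root_position(self) -> np.ndarray:
        """Soma attach point: position of the first root node."""
        return self.nodes[self.root_ids[0]].position

    def _anchor_ids(self) -> set[int]:
        """Nodes at which branches start: soma nodes and forks (>=2 children)."""
        anchors = set(self.soma_ids)
        for i, ch in self.children.items():
            dend_children = [c for c in ch if self.nodes[c].kind == DENDRITE]
            if len(dend_children) >= 2:
                anchors.add(i)
            if self.nodes[i].parent_id is None and self.nodes[i].kind == DENDRITE:
                anchors.add(i)
        return anchors

    @property
    def branches(self) -> list[Branch]:
        if self._branches is None:
            self._branches = self._extract_branches()
        return self._branches

    def _invalidate(self) -> None:
        self._branches = None

    def _extract_branches(self) -> list[Branch]:
        anchors = self._anchor_ids()
        branches: list[Branch] = []
        # depth-first from the start anchors so that a fork's incoming branch
        # exists before its outgoing branches reference it as parent
        start_anchors = sorted(
            a for a in anchors
            if self.nodes[a].kind == SOMA or self.nodes[a].parent_id is None
        )
        stack: list[tuple[int, int | None]] = [(a, None) for a in reversed(start_anchors)]
        while stack:
            a, parent_branch = stack.pop()
            for c in sorted(self.children[a]):
                if self.nodes[c].kind != DENDRITE:
                    continue
                path = [a, c]
                while (
                    path[-1] not in anchors
                    and len(self.children[path[-1]]) == 1
                    and self.nodes[self.children[path[-1]][0]].kind == DENDRITE
                ):
                    path.append(self.children[path[-1]][0])
                bid = len(branches)
                segs = [
                    Segment(
                        self.nodes[u].position,
                        self.nodes[v].position,
                        self.nodes[v].radius,
                        bid,
                    )
                    for u, v in zip(path[:-1], path[1:])
                ]
                branches.append(
                    Branch(segs, branch_id=bid, node_ids=path, parent_branch=parent_branch)
                )
                end = path[-1]
                if end in anchors and self.nodes[end].kind == DENDRITE:
                    stack.append((end, bid))
        return branches

    @property
    def segments(self) -> list[Segment]:
        return [s for b in self.branches for s in b.segments]

    @property
    def L_max(self) -> float:
        """Longest branch length (µm)."""
        if not self.branches:
            raise StructureError("arbor has no branches")
        return max(b.length for b in self.branches)

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    def segment_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, radii) stacked over all segments, in branch order."""
        segs = self.segments
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        radii = np.array([s.radius for s in segs])
        return starts, ends, radii

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "CenterlineArbor":
        """Rigidly transformed copy (rotation about the origin, then shift)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        nodes = [
            CenterlineNode(n.id, R @ n.position + t, n.radius, n.parent_id, n.kind)
            for n in self.nodes.values()
        ]
        return CenterlineArbor(nodes)


@dataclass
class TriangleMesh:
    """Triangle surface mesh with an optional face→segment mapping.

    ``segment_of_face[i]`` gives the index (into the generating arbor's
    segment list) of the tube piece face ``i`` belongs to, or -1 when the
    mesh was not built from a centerline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    segment_of_face: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshFormatError("face index out of range")
        if self.segment_of_face is not None:
            self.segment_of_face = np.asarray(self.segment_of_face, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        """Raw surface area (sum of triangle areas, no interior exclusion)."""
        v = self.vertices[self.faces]
        cr = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return float(0.5 * np.linalg.norm(cr, axis=1).sum())

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class VoxelGrid:
    """Sparse occupancy grid: integer voxel coords ≥ 0 plus origin/resolution."""

    resolution: float  #: voxels per µm
    origin: np.ndarray  #: µm position of the min corner of voxel (0,0,0)
    coords: np.ndarray  #: (N, 3) unique integer voxel coordinates

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.resolution <= 0:
            raise ParameterError("resolution must be > 0")
        if len(self.coords) and self.coords.min() < 0:
            raise ParameterError("voxel coordinates must be non-negative")

    @property
    def voxel_side(self) -> float:
        return 1.0 / self.resolution

    @property
    def n_occupied(self) -> int:
        return len(self.coords)

    def extent_voxels(self) -> np.ndarray:
        if not len(self.coords):
            return np.zeros(3, dtype=np.int64)
        return self.coords.max(axis=0) + 1

    def longest_side_um(self) -> float:
        return float(self.extent_voxels().max() * self.voxel_side)

    def centers_um(self) -> np.ndarray:
        """Voxel center positions in µm (absolute coordinates)."""
        return self.origin + (self.coords + 0.5) * self.voxel_side

    def to_csv(self, path) -> None:
        np.savetxt(path, self.coords, fmt="%d", delimiter=",", header="x,y,z", comments="")


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> CenterlineArbor:
    """Read a standard 7-column SWC file into a :class:`CenterlineArbor`.

    Samples typed 1 are soma; every other type is treated as dendrite.
    Soma samples are kept in the tree (as attachment points) but excluded
    from branch statistics downstream.
    """
    nodes: list[CenterlineNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCFormatError(f"line {lineno}: expected 7 fields, got {len(parts)}")
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z, radius = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCFormatError(f"line {lineno}: {exc}") from None
            kind = SOMA if ntype == _SWC_TYPE_SOMA else DENDRITE
            nodes.append(
                CenterlineNode(
                    nid, np.array([x, y, z]), radius,
                    None if parent == -1 else parent, kind,
                )
            )
    if not nodes:
        raise SWCFormatError("SWC file contains no samples")
    return CenterlineArbor(nodes)


def write_swc(arbor: CenterlineArbor, path) -> None:
    """Write an arbor back to SWC (soma rows typed 1, dendrites typed 3)."""
    if not arbor.nodes:
        raise StructureError("refusing to write an empty arbor")
    with open(path, "w") as fh:
        fh.write("# SWC written by fractalarbor\n")
        for nid in sorted(arbor.nodes):
            n = arbor.nodes[nid]
            t = _SWC_TYPE_SOMA if n.kind == SOMA else _SWC_TYPE_DENDRITE
            p = -1 if n.parent_id is None else n.parent_id
            fh.write(
                f"{n.id} {t} {n.position[0]:.9g} {n.position[1]:.9g} "
                f"{n.position[2]:.9g} {n.radius:.9g} {p}\n"
            )


# ---------------------------------------------------------------------------
# OBJ I/O (via trimesh; non-triangular faces are fan-triangulated)
# ---------------------------------------------------------------------------

def read_obj_mesh(path) -> TriangleMesh:
    """Read a Wavefront OBJ surface into a :class:`TriangleMesh`."""
    try:
        tm = _trimesh.load(str(path), file_type="obj", process=False, force="mesh")
    except (ValueError, IndexError, KeyError) as exc:
        raise MeshFormatError(f"could not parse OBJ: {exc}") from None
    if tm.faces.size and tm.faces.max() >= len(tm.vertices):
        raise MeshFormatError("face index out of range")
    return TriangleMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


def write_obj_mesh(mesh: TriangleMesh, path) -> None:
    mesh.to_trimesh().export(str(path), file_type="obj", include_normals=False)


# ---------------------------------------------------------------------------
# Mesh synthesis from a centerline
# ---------------------------------------------------------------------------

def mesh_from_centerline(arbor: CenterlineArbor, ring_points: int = RING_POINTS) -> TriangleMesh:
    """Build the tube surface mesh of an arbor.

    Each segment contributes two rings of ``ring_points`` vertices and
    ``2*ring_points`` side faces; terminal segments additionally carry a
    fan end cap of ``ring_points - 2`` faces.  A child branch re-uses its
    parent's final ring so tubes remain connected across forks, and ring
    frames are parallel-transported along branches to avoid twist.
    """
    if ring_points < 3:
        raise ParameterError("ring_points must be >= 3")
    branches = arbor.branches
    if not branches:
        raise StructureError("arbor has no branches to mesh")

    phis = 2.0 * np.pi * np.arange(ring_points) / ring_points
    cos_p, sin_p = np.cos(phis), np.sin(phis)

    # reference direction derived from the arbor's own geometry so that the
    # construction commutes with rigid rotations (a fixed world axis would
    # twist rings differently after rotating the arbor)
    seg_dirs = [s.direction for s in arbor.segments]
    e_ref = None
    for d in seg_dirs[1:]:
        c = np.cross(seg_dirs[0], d)
        n = np.linalg.norm(c)
        if n > 1e-8:
            e_ref = c / n
            break
    if e_ref is None:  # perfectly collinear arbor: twist is immaterial
        e_ref = _geom.perpendicular_vector(seg_dirs[0])

    def initial_inplane(m0: np.ndarray) -> np.ndarray:
        e = e_ref - m0 * np.dot(e_ref, m0)
        n = np.linalg.norm(e)
        if n > 1e-8:
            return e / n
        e = np.cross(m0, seg_dirs[0])
        n = np.linalg.norm(e)
        if n > 1e-8:
            return e / n
        return _geom.perpendicular_vector(m0)

    vertices: list[np.ndarray] = []
    faces: list[np.ndarray] = []
    seg_of_face: list[np.ndarray] = []
    # per-branch end state for children to pick up: (ring vertex indices, frame)
    end_state: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    seg_index = 0  # global segment counter aligned with arbor.segments order

    n_verts = 0

    def add_ring(center, radius, m, e1) -> np.ndarray:
        nonlocal n_verts
        e2 = np.cross(m, e1)
        ring = center + radius * (np.outer(cos_p, e1) + np.outer(sin_p, e2))
        vertices.append(ring)
        base = n_verts
        n_verts += ring_points
        return base + np.arange(ring_points)

    child_count: dict[int, int] = {}
    for b in branches:
        if b.parent_branch is not None:
            child_count[b.parent_branch] = child_count.get(b.parent_branch, 0) + 1

    for b in branches:
        pts = [b.segments[0].start] + [s.end for s in b.segments]
        dirs = [s.direction for s in b.segments]
        radii = [b.segments[0].radius] + [s.radius for s in b.segments]
        k = len(b.segments)

        if b.parent_branch is not None and b.parent_branch in end_state:
            ring0, m_prev, e1_prev = end_state[b.parent_branch]
            prev_idx = ring0
        else:
            m0 = dirs[0]
            e1 = initial_inplane(m0)
            prev_idx = add_ring(pts[0], radii[0], m0, e1)
            m_prev, e1_prev = m0, e1

        for j in range(k):
            d = dirs[j]
            if j < k - 1:
                m = _bisector(dirs[j], dirs[j + 1])
            else:
                m = d
            # transport the in-plane frame from the previous ring normal
            R = _geom.minimal_rotation_to(m_prev, m)
            e1 = R @ e1_prev
            e1 = e1 - m * np.dot(e1, m)
            e1 /= np.linalg.norm(e1)
            cur_idx = add_ring(pts[j + 1], radii[j + 1], m, e1)
            f = _ring_faces(prev_idx, cur_idx, ring_points)
            faces.append(f)
            seg_of_face.append(np.full(len(f), seg_index, dtype=np.int64))
            if j == k - 1:
                end_state[b.branch_id] = (cur_idx, m, e1)
                if child_count.get(b.branch_id, 0) == 0:
                    cap = _cap_faces(cur_idx)
                    faces.append(cap)
                    seg_of_face.append(np.full(len(cap), seg_index, dtype=np.int64))
            prev_idx, m_prev, e1_prev = cur_idx, m, e1
            seg_index += 1

    V = np.concatenate(vertices, axis=0)
    F = np.concatenate(faces, axis=0)
    S = np.concatenate(seg_of_face, axis=0)
    return TriangleMesh(V, F, S)


def _bisector(d0: np.ndarray, d1: np.ndarray) -> np.ndarray:
    s = d0 + d1
    n = np.linalg.norm(s)
    if n < 1e-9:  # hairpin: fall back to the outgoing direction
        return d1
    return s / n


def _ring_faces(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    i = np.arange(n)
    j = (i + 1) % n
    tri1 = np.stack([a[i], a[j], b[i]], axis=1)
    tri2 = np.stack([a[j], b[j], b[i]], axis=1)
    return np.concatenate([tri1, tri2], axis=0)


def _cap_faces(ring: np.ndarray) -> np.ndarray:
    """Fan triangulation of the terminal ring: n-2 faces."""
    n = len(ring)
    i = np.arange(1, n - 1)
    return np.stack([np.full(n - 2, ring[0]), ring[i], ring[i + 1]], axis=1)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def voxelize(mesh: TriangleMesh, resolution: float, fill_interior: bool = False,
             _chunk: int = 2_000_000) -> VoxelGrid:
    """Exact (conservative) surface voxelization of a triangle mesh.

    A voxel is occupied iff at least one face intersects its cube
    (separating-axis triangle/box test; touching counts).  With
    ``fill_interior`` voxels fully enclosed by the surface are added as
    well (flood fill of the complement from the grid boundary).
    """
    if resolution <= 0:
        raise ParameterError("resolution must be > 0")
    if mesh.n_faces == 0:
        raise MeshFormatError("cannot voxelize an empty mesh")
    lo, hi = mesh.bounds()
    origin = lo
    n_vox = np.maximum(np.ceil((hi - lo) * resolution).astype(np.int64), 1)

    tri = mesh.vertices[mesh.faces] - origin  # local µm coordinates
    tri_v = tri * resolution  # voxel units
    tlo = np.floor(tri_v.min(axis=1)).astype(np.int64)
    thi = np.floor(tri_v.max(axis=1)).astype(np.int64) + 1
    tlo = np.clip(tlo, 0, n_vox - 1)
    thi = np.clip(thi, 1, n_vox)

    counts = np.prod(thi - tlo, axis=1)
    occupied: list[np.ndarray] = []
    # chunk triangles so (triangle, candidate) pair arrays stay bounded
    csum = np.cumsum(counts)
    start = 0
    while start < len(counts):
        base = csum[start - 1] if start else 0
        stop = int(np.searchsorted(csum, base + _chunk)) + 1
        stop = min(max(stop, start + 1), len(counts))
        sel = slice(start, stop)
        occupied.append(_voxelize_chunk(tri_v[sel], tlo[sel], thi[sel]))
        start = stop
    coords = _geom.unique_rows(np.concatenate(occupied, axis=0))
    grid = VoxelGrid(resolution, origin, coords)
    if fill_interior:
        grid = _fill_enclosed(grid)
    return grid


def voxelize_centerline(arbor: CenterlineArbor, resolution: float,
                        step: float = 0.25) -> VoxelGrid:
    """Voxelize the centerline skeleton (zero-width) of an arbor.

    Segments are sampled every ``step`` µm and the voxels containing the
    samples are marked.  This exposes the arbor's branching/weaving
    geometry without the fattening contributed by the tube width, which
    is the preferred substrate for estimating the scaling exponent of
    generated trees whose branch width is a nuisance parameter.
    """
    if resolution <= 0 or step <= 0:
        raise ParameterError("resolution and step must be > 0")
    starts, ends, _ = arbor.segment_arrays()
    pts = []
    for s, e in zip(starts, ends):
        L = np.linalg.norm(e - s)
        n = max(2, int(np.ceil(L / step)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        pts.append(s + (e - s) * t)
    allpts = np.concatenate(pts, axis=0)
    lo = allpts.min(axis=0)
    coords = np.floor((allpts - lo) * resolution).astype(np.int64)
    return VoxelGrid(resolution, lo, _geom.unique_rows(coords))


def _voxelize_chunk(tri_v, tlo, thi) -> np.ndarray:
    spans = thi - tlo
    nx, ny, nz = spans[:, 0], spans[:, 1], spans[:, 2]
    per_tri = nx * ny * nz
    owner = np.repeat(np.arange(len(tri_v)), per_tri)
    # local linear index within each triangle's candidate block
    offs = np.arange(len(owner)) - np.repeat(
        np.concatenate(([0], np.cumsum(per_tri)[:-1])), per_tri
    )
    oy = ny[owner] * nz[owner]
    ix = offs // oy
    rem = offs - ix * oy
    iy = rem // nz[owner]
    iz = rem - iy * nz[owner]
    cand = np.stack([ix, iy, iz], axis=1) + tlo[owner]
    centers = cand + 0.5
    mask = _geom.triangle_box_overlap(tri_v[owner], centers, 0.5)
    return cand[mask]


def _fill_enclosed(grid: VoxelGrid) -> VoxelGrid:
    from scipy import ndimage

    shape = tuple(grid.extent_voxels())
    if np.prod(shape) > 1_500_000_000:
        raise ParameterError("grid too large for dense interior fill")
    dense = np.zeros(shape, dtype=bool)
    dense[tuple(grid.coords.T)] = True
    filled = ndimage.binary_fill_holes(dense)
    coords = np.argwhere(filled)
    return VoxelGrid(grid.resolution, grid.origin, coords)
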