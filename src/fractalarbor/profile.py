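"""Connectivity-profile analysis: dilation, viewpoints, projected areas.

The profile P of an arbor from a viewing direction is the total area of
its orthographic shadow on a 1 µm² lattice: occupied voxel centers are
rotated so the view direction becomes the projection axis, projected,
rounded, and duplicate cells are counted once — branches that hide
behind one another contribute a single cell, which is exactly the
redundancy-discounting the profile is meant to capture.  Before
projecting, the arbor is uniformly dilated by the spine reach (2 µm by
default) so dendritic spines can contribute synapses; P is therefore
allowed to exceed the membrane area A_s.

Orientation averages use a Fibonacci (golden-angle) lattice of
viewpoints on the sphere: 201 directions suffice for <1% convergence of
the mean profile; 10,001 are used for visualization maps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geom
from .arbor import VoxelGrid
from .errors import ParameterError

__all__ = [
    "ViewpointSet",
    "ProfileResult",
    "fibonacci_directions",
    "dilate_grid",
    "project_area",
    "mean_profile",
    "profile_sphere_map",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_VIEW_AXIS = np.array([0.0, 0.0, -1.0])


@dataclass
class ViewpointSet:
    directions: np.ndarray  #: (n, 3) unit vectors

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ParameterError("viewpoint directions must be unit vectors")

    @property
    def count(self) -> int:
        return len(self.directions)


@dataclass
class ProfileResult:
    per_direction: np.ndarray   #: P (µm²) per viewpoint
    mean_P: float
    argmax_direction: np.ndarray
    P_over_As: float | None = None
    P_over_Ab: float | None = None


def fibonacci_directions(n: int) -> ViewpointSet:
    """Golden-angle lattice of ``n`` near-uniform directions on the sphere."""
    if n < 1:
        raise ParameterError("need at least one viewpoint")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    az = k * _GOLDEN_ANGLE
    return ViewpointSet(np.stack([r * np.cos(az), r * np.sin(az), z], axis=1))


def dilate_grid(grid: VoxelGrid, radius: float = 2.0) -> VoxelGrid:
    """Union of Euclidean balls of ``radius`` µm around occupied voxels.

    Membership is by voxel-center distance, so a single voxel dilated by
    2 µm at 1 voxel/µm grows to the 33 lattice points with x²+y²+z² ≤ 4.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    if radius == 0 or grid.n_occupied == 0:
        return VoxelGrid(grid.resolution, grid.origin.copy(), grid.coords.copy())
    r_vox = radius * grid.resolution
    m = int(np.floor(r_vox))
    ax = np.arange(-m, m + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    offs = offs[np.einsum("ij,ij->i", offs, offs) <= r_vox * r_vox + 1e-9]

    out = []
    chunk = max(1, 4_000_000 // len(offs))
    for lo in range(0, grid.n_occupied, chunk):
        c = grid.coords[lo:lo + chunk]
        out.append(_geom.unique_rows((c[:, None, :] + offs[None, :, :]).reshape(-1, 3)))
    coords = _geom.unique_rows(np.concatenate(out, axis=0))
    shift = coords.min(axis=0)
    return VoxelGrid(
        grid.resolution,
        grid.origin + shift * grid.voxel_side,
        coords - shift,
    )


def _projected_cells(points_um: np.ndarray, direction: np.ndarray,
                     spacing: float) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ParameterError("zero view direction")
    R = _geom.minimal_rotation_to(d / nrm, _VIEW_AXIS)
    rot = points_um @ R.T
    rot = rot - rot.mean(axis=0)  # lattice anchored at the rotated centroid
    # round half-up: np.round's half-to-even would merge adjacent cells on
    # exactly-half-integer lattices (axis-aligned views of voxel centers);
    # the epsilon absorbs 1-ulp rotation noise at exact cell boundaries
    return np.floor(rot[:, :2] / spacing + 0.5 + 1e-9).astype(np.int64)


def _shadow_count(points_um: np.ndarray, direction: np.ndarray,
                  voxel_side: float, cell_um: float) -> int:
    """Distinct shadow cells of size ``cell_um``.

    At ``voxel_side == cell_um`` this is the classic round-and-dedupe
    count.  With a finer grid, a cell is counted only when its *center*
    is covered (some point rounds into the central sub-cell), which
    removes the rim inflation of ~0.35 µm per silhouette edge that the
    coarse rule suffers on convex bodies.
    """
    m = max(1, int(round(cell_um / voxel_side)))
    q = _projected_cells(points_um, direction, voxel_side)
    if m > 1:
        q = q[np.all(q % m == 0, axis=1)] // m
    return _geom.count_unique_rows(q)


def project_area(grid: VoxelGrid, direction: np.ndarray, cell_um: float = 1.0) -> float:
    """Shadow area P (µm²) of the grid seen along ``direction``."""
    if grid.n_occupied == 0:
        return 0.0
    n = _shadow_count(grid.centers_um(), direction, grid.voxel_side, cell_um)
    return float(n) * cell_um**2


def mean_profile(
    grid: VoxelGrid,
    viewpoints: ViewpointSet,
    A_s: float | None = None,
    A_b: float | None = None,
    cell_um: float = 1.0,
) -> ProfileResult:
    """Orientation-averaged profile over a viewpoint set."""
    if viewpoints.count == 0:
        raise ParameterError("empty viewpoint set")
    pts = grid.centers_um()
    P = np.empty(viewpoints.count)
    for i, d in enumerate(viewpoints.directions):
        P[i] = _shadow_count(pts, d, grid.voxel_side, cell_um) * cell_um**2
    mean_P = float(P.mean())
    return ProfileResult(
        per_direction=P,
        mean_P=mean_P,
        argmax_direction=viewpoints.directions[int(np.argmax(P))],
        P_over_As=mean_P / A_s if A_s else None,
        P_over_Ab=mean_P / A_b if A_b else None,
    )


def profile_sphere_map(grid: VoxelGrid, n: int = 10001) -> tuple[np.ndarray, np.ndarray]:
    """(directions, P) pairs on an ``n``-point lattice, for profile spheres."""
    vp = fibonacci_directions(n)
    res = mean_profile(grid, vp)
    return vp.directions, res.per_direction
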