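"""Low-level vectorized geometry kernels shared across modules.

Everything in here operates on plain numpy arrays; the public modules wrap
these in the domain types.  Conventions: positions are continuous µm
coordinates, voxel indices are integers, rotations are right-handed.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "perpendicular_vector",
    "rotation_about_axis",
    "minimal_rotation_to",
    "pack_rows",
    "unique_rows",
    "count_unique_rows",
    "expand_ranges",
    "triangle_box_overlap",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize the last axis of ``v``; raises on zero vectors."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def perpendicular_vector(d: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to unit vector ``d`` (deterministic choice)."""
    d = np.asarray(d, dtype=float)
    # pick the world axis least aligned with d to avoid degeneracy
    a = np.zeros(3)
    a[np.argmin(np.abs(d))] = 1.0
    p = np.cross(d, a)
    return p / np.linalg.norm(p)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit ``axis`` and angle in radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)


def minimal_rotation_to(d: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix sending unit vector ``d`` onto unit ``target``.

    At the antipode (d ≈ -target) the rotation plane is ambiguous; a fixed
    180° rotation about the x-axis (or y if x is parallel) is used so the
    map stays deterministic.
    """
    d = np.asarray(d, dtype=float)
    target = np.asarray(target, dtype=float)
    c = float(np.dot(d, target))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        ax = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ax, d)) > 1.0 - 1e-9:
            ax = np.array([0.0, 1.0, 0.0])
        # remove the component along d so the axis is perpendicular
        ax = ax - d * np.dot(ax, d)
        return rotation_about_axis(ax, np.pi)
    axis = np.cross(d, target)
    s = np.linalg.norm(axis)
    return rotation_about_axis(axis / s, float(np.arctan2(s, c)))


def pack_rows(coords: np.ndarray) -> np.ndarray:
    """Pack integer rows (N, k) into int64 keys (collision free).

    Coordinates are shifted to be non-negative, then mixed with row strides.
    """
    coords = np.asarray(coords)
    if coords.ndim != 2:
        raise ValueError("expected a 2-D integer array")
    lo = coords.min(axis=0)
    shifted = (coords - lo).astype(np.int64)
    spans = shifted.max(axis=0) + 1
    key = shifted[:, 0]
    for j in range(1, coords.shape[1]):
        key = key * spans[j] + shifted[:, j]
    return key


def unique_rows(coords: np.ndarray) -> np.ndarray:
    """Deduplicate integer rows, preserving no particular order cheaply."""
    coords = np.asarray(coords)
    if len(coords) == 0:
        return coords
    key = pack_rows(coords)
    _, idx = np.unique(key, return_index=True)
    return coords[idx]


def count_unique_rows(coords: np.ndarray) -> int:
    if len(coords) == 0:
        return 0
    key = pack_rows(coords)
    key.sort()
    return int(1 + np.count_nonzero(np.diff(key)))


def expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate ragged integer ranges ``[lo_i, hi_i)`` flattened.

    Returns (owner, value): ``value[k]`` runs over each range and
    ``owner[k]`` indexes the source row.  Used to expand per-triangle voxel
    candidate ranges without a Python loop.
    """
    lo = np.asarray(lo, dtype=np.int64)
    hi = np.asarray(hi, dtype=np.int64)
    counts = np.maximum(hi - lo, 0)
    total = int(counts.sum())
    owner = np.repeat(np.arange(len(lo)), counts)
    if total == 0:
        return owner, np.empty(0, dtype=np.int64)
    # value = arange within each segment
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    value = np.arange(total) - np.repeat(starts, counts) + np.repeat(lo, counts)
    return owner, value


def triangle_box_overlap(tri: np.ndarray, centers: np.ndarray, half: float) -> np.ndarray:
    """Separating-axis triangle / axis-aligned-cube overlap test (vectorized).

    Parameters
    ----------
    tri : (M, 3, 3) triangle vertices.
    centers : (M, 3) cube centers, one per triangle.
    half : scalar half-extent of the cubes.

    Returns a boolean mask of overlapping pairs.  Boxes are treated as
    closed, i.e. touching counts as overlap (conservative).
    """
    v = tri - centers[:, None, :]  # vertices relative to box center
    ok = np.ones(len(v), dtype=bool)

    # 1. box face normals (AABB test)
    mx = v.max(axis=1)
    mn = v.min(axis=1)
    ok &= np.all(mn <= half + 1e-12, axis=1) & np.all(mx >= -half - 1e-12, axis=1)

    # 2. triangle plane
    f0 = v[:, 1] - v[:, 0]
    f1 = v[:, 2] - v[:, 1]
    f2 = v[:, 0] - v[:, 2]
    n = np.cross(f0, f1)
    d = np.einsum("ij,ij->i", n, v[:, 0])
    r = half * np.abs(n).sum(axis=1)
    ok &= np.abs(d) <= r + 1e-12

    # 3. nine edge cross-product axes
    for f in (f0, f1, f2):
        for ax in range(3):
            a = np.zeros_like(f)
            # axis = e_ax x f  -> components
            a[:, (ax + 1) % 3] = -f[:, (ax + 2) % 3]
            a[:, (ax + 2) % 3] = f[:, (ax + 1) % 3]
            p = np.einsum("ijk,ik->ij", v, a)
            rad = half * np.abs(a).sum(axis=1)
            ok &= (p.min(axis=1) <= rad + 1e-12) & (p.max(axis=1) >= -rad - 1e-12)
    return ok
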