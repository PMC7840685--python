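"""3-D sliding box count and effective fractal dimension estimation.

Fractal scaling follows the power law N_box ~ L_box^-D.  The counter
covers the voxelized arbor with an axis-aligned partition of cubic boxes
of side L_box, slides the partition diagonally (all three axes shifted
simultaneously) in fixed steps, and keeps the minimum occupied-box count
— the standard guard against arbitrary grid placement inflating counts.

The dimension is fitted in log-log space over the admissible window
[2 µm, L/5] where L is the longest bounding-box side: above L/5 there
are fewer than five boxes per side and every box fills (slope drifts to
3); below ~2 µm the boxes resolve the tube surfaces of the branches
(slope drifts to 2).  Within the window, every contiguous point range
spanning at least one decade is fitted and the fit maximizing R² wins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import pack_rows
from .arbor import VoxelGrid
from .errors import InsufficientScalingRangeError, ParameterError

__all__ = [
    "BoxCountCurve",
    "DimensionFit",
    "default_box_sizes",
    "box_count",
    "fit_dimension",
    "measure_dimension",
]

#: lower fit bound (µm): box sizes comparable to branch diameters probe
#: the 2-D tube surface, not the arbor's fractal arrangement
FINE_CUTOFF_UM = 2.0
#: require at least this many boxes per bounding-box side at the coarse end
COARSE_MIN_BOXES = 5


@dataclass
class BoxCountCurve:
    box_sizes: np.ndarray     #: L_box (µm), increasing
    counts: np.ndarray        #: minimum occupied-box count per size
    L_max_side: float         #: longest bounding-box side (µm)

    def __post_init__(self):
        self.box_sizes = np.asarray(self.box_sizes, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)


@dataclass
class DimensionFit:
    D: float
    r_squared: float
    fit_range_um: tuple[float, float]
    fit_range_rel: tuple[float, float]   #: normalized by L_max_side
    n_points: int


def default_box_sizes(grid: VoxelGrid, n_sizes: int = 24) -> np.ndarray:
    """Geometric ladder of box sizes from one voxel to the bounding box.

    Sizes are snapped to whole voxel multiples (so box boundaries always
    coincide with voxel boundaries) and deduplicated; at least two sizes
    are returned even for tiny grids.
    """
    side = grid.voxel_side
    top = max(grid.longest_side_um(), 2.0 * side)
    sizes = np.geomspace(side, top, n_sizes)
    vox = np.unique(np.maximum(np.round(sizes / side).astype(np.int64), 1))
    return vox * side


def box_count(
    grid: VoxelGrid,
    box_sizes: np.ndarray | None = None,
    slide_step: float = 0.25,
    max_offsets: int = 64,
) -> BoxCountCurve:
    """Sliding box count: minimum occupied-box count over diagonal offsets.

    ``slide_step`` is in µm (snapped to whole voxels, at least one); the
    number of offsets per box size is capped at ``max_offsets`` (evenly
    thinned) to keep large boxes tractable.
    """
    if grid.n_occupied == 0:
        raise ParameterError("grid is empty")
    if box_sizes is None:
        box_sizes = default_box_sizes(grid)
    box_sizes = np.asarray(box_sizes, dtype=float)
    side = grid.voxel_side
    if np.any(box_sizes < side - 1e-12):
        raise ParameterError("box size smaller than the voxel side")
    sizes_vox = np.unique(np.maximum(np.round(box_sizes / side).astype(np.int64), 1))
    step_vox = max(1, int(round(slide_step / side)))

    coords = grid.coords
    counts = np.empty(len(sizes_vox), dtype=np.int64)
    for si, b in enumerate(sizes_vox):
        offs = np.arange(0, b, step_vox, dtype=np.int64)
        if len(offs) > max_offsets:
            keep = np.unique(np.linspace(0, len(offs) - 1, max_offsets).astype(int))
            offs = offs[keep]
        best = None
        for o in offs:
            boxes = (coords + o) // b
            key = pack_rows(boxes)
            key.sort()
            n = int(1 + np.count_nonzero(np.diff(key)))
            if best is None or n < best:
                best = n
        counts[si] = best
    return BoxCountCurve(sizes_vox * side, counts, grid.longest_side_um())


def fit_dimension(
    curve: BoxCountCurve,
    min_box_um: float = FINE_CUTOFF_UM,
    min_decades: float = 1.0,
    min_points: int = 4,
) -> DimensionFit:
    """Best-R² power-law fit over ≥ one decade inside the admissible window.

    Raises :class:`InsufficientScalingRangeError` when the window
    [min_box_um, L_max_side/5] holds fewer than ``min_points`` sizes or
    spans less than ``min_decades`` decades.  Ties in R² are broken in
    favor of the wider range.
    """
    hi = curve.L_max_side / COARSE_MIN_BOXES
    mask = (curve.box_sizes >= min_box_um - 1e-9) & (curve.box_sizes <= hi + 1e-9)
    sizes = curve.box_sizes[mask]
    counts = curve.counts[mask]
    if len(sizes) < min_points or sizes[-1] / sizes[0] < 10.0**min_decades * (1 - 1e-9):
        raise InsufficientScalingRangeError(
            f"admissible window [{min_box_um:g}, {hi:g}] µm holds {len(sizes)} sizes "
            f"spanning {np.log10(sizes[-1]/sizes[0]) if len(sizes) else 0:.2f} decades "
            f"(need >= {min_points} and >= {min_decades:g})"
        )
    x = np.log10(sizes)
    y = np.log10(counts.astype(float))

    best: tuple[float, float, int, int] | None = None  # (r2, width, i, j)
    n = len(x)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            if x[j] - x[i] < min_decades * (1 - 1e-9):
                continue
            xi, yi = x[i:j + 1], y[i:j + 1]
            slope, intercept = np.polyfit(xi, yi, 1)
            resid = yi - (slope * xi + intercept)
            ss_tot = float(np.sum((yi - yi.mean()) ** 2))
            r2 = 1.0 if ss_tot < 1e-30 else 1.0 - float(np.sum(resid**2)) / ss_tot
            width = x[j] - x[i]
            cand = (r2, width, i, j)
            if best is None or (r2, width) > (best[0], best[1]):
                best = cand
    r2, width, i, j = best
    slope = np.polyfit(x[i:j + 1], y[i:j + 1], 1)[0]
    return DimensionFit(
        D=float(-slope),
        r_squared=float(r2),
        fit_range_um=(float(sizes[i]), float(sizes[j])),
        fit_range_rel=(float(sizes[i] / curve.L_max_side), float(sizes[j] / curve.L_max_side)),
        n_points=j - i + 1,
    )


def measure_dimension(grid: VoxelGrid, **kwargs) -> DimensionFit:
    """Convenience: default box sizes → sliding count → best-decade fit."""
    fit_kwargs = {k: kwargs.pop(k) for k in list(kwargs)
                  if k in ("min_box_um", "min_decades", "min_points")}
    curve = box_count(grid, **kwargs)
    return fit_dimension(curve, **fit_kwargs)
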