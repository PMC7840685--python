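"""Generators for all synthetic study inputs.

H-trees are binary fractal trees whose branch lengths shrink geometrically
between levels,

    L_i = L_1 / 2^((i-1)/D),

so the scaling exponent ``D`` is set directly by the shrink factor.  The
level-1 branch emanates from the soma; level ``i`` holds ``2^(i-1)``
branches.  3D trees rotate the branching plane by 90° about the parent
axis at each level so the fork planes cycle through space.  Weaving
variants bend each branch with angles drawn from a fractional Gaussian
noise (fGn) sequence — a self-similar stationary process — scaled to a
requested standard deviation; bending preserves arc length.

Toy arbors emulate pyramidal-cell basal/apical dendrites statistically:
log-normal segment lengths and widths, half-normal weave and fork angles,
with medians anchored to measured values (θ ≈ 12°, ϕ ≈ 37°, segment
length ≈ 2.4 µm, width ≈ 1.4 µm).  Only the medians are matched; the full
joint distribution of real reconstructions is out of scope.

Euclidean fixtures (sphere, cube, line) provide the D = 3 / D = 2 / D = 1
reference geometries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import trimesh as _trimesh

from . import _geom
from .arbor import CenterlineArbor, CenterlineNode, SOMA, TriangleMesh
from .errors import ParameterError

_GOLDEN_ANGLE_RAD = np.pi * (3.0 - np.sqrt(5.0))

__all__ = [
    "HTreeSpec",
    "ToyArborSpec",
    "generate_htree",
    "generate_weaving_htree",
    "generate_equal_length_htree",
    "equalize_htree",
    "generate_toy_arbor",
    "generate_sphere_mesh",
    "generate_cube_mesh",
    "generate_line_arbor",
    "htree_level_lengths",
    "fractional_gaussian_noise",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HTreeSpec:
    """Parameters of an H-tree; exactly one of ``L_1``/``total_length`` set.

    ``weave_sigma`` is the standard deviation of the weave-angle
    distribution in degrees (0 = straight branches); ``hurst`` is the fGn
    Hurst exponent (the weave process is self-similar for any value in
    (0, 1); 0.75 is the documented default, not a claimed measurement).
    """

    D_target: float
    levels: int = 12
    L_1: float | None = None
    total_length: float | None = None
    width: float = 1.0
    dimensionality: Literal["2D", "3D"] = "3D"
    weave_sigma: float = 0.0
    hurst: float = 0.75
    seed: int = 0
    segment_length: float | None = None  #: weave granularity; default = width

    def __post_init__(self):
        if self.D_target <= 0:
            raise ParameterError("D_target must be > 0")
        if self.levels < 1:
            raise ParameterError("levels must be >= 1")
        if (self.L_1 is None) == (self.total_length is None):
            raise ParameterError("specify exactly one of L_1 or total_length")
        if self.width <= 0:
            raise ParameterError("width must be > 0")
        if not (0.0 < self.hurst < 1.0):
            raise ParameterError("hurst must lie in (0, 1)")
        if self.weave_sigma < 0:
            raise ParameterError("weave_sigma must be >= 0")


@dataclass(frozen=True)
class ToyArborSpec:
    """Statistical description of a neuron-like random arbor."""

    n_levels: int
    theta_median: float = 12.0
    phi_median: float = 37.0
    segment_length_median: float = 2.4
    width_median: float = 1.4
    seed: int = 0
    n_primary: int = 3
    segments_per_branch_median: float = 12.0
    fork_probability: float = 0.9

    def __post_init__(self):
        if self.n_levels < 1:
            raise ParameterError("n_levels must be >= 1")
        for name in ("theta_median", "phi_median"):
            v = getattr(self, name)
            if not (0.0 < v < 180.0):
                raise ParameterError(f"{name} must lie in (0°, 180°)")
        for name in ("segment_length_median", "width_median"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


def htree_level_lengths(spec: HTreeSpec) -> np.ndarray:
    """Branch length per level, honoring the L_1/total_length alternative.

    With ``total_length`` given, L_1 is solved from
    sum_i 2^(i-1) * L_i = total, keeping total wire constant across D.
    """
    i = np.arange(1, spec.levels + 1)
    scale = 2.0 ** (-(i - 1) / spec.D_target)
    if spec.L_1 is not None:
        L1 = spec.L_1
    else:
        # sum of 2^(i-1) * scale_i
        weight = float(np.sum(2.0 ** (i - 1) * scale))
        L1 = spec.total_length / weight
    return L1 * scale


# ---------------------------------------------------------------------------
# fractional Gaussian noise (Davies–Harte circulant embedding)
# ---------------------------------------------------------------------------

def fractional_gaussian_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` points of unit-variance fGn with the given Hurst exponent."""
    if not (0.0 < hurst < 1.0):
        raise ParameterError("hurst must lie in (0, 1)")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(n)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    # circulant embedding of the covariance
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    eig = np.clip(eig, 0.0, None)  # numerical negatives
    m = len(row)
    z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2)
    if m % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2)
    # X = Re FFT( sqrt(eig/(2m)) Z ); irfft carries 1/m, undo it
    w = np.fft.irfft(np.sqrt(eig / (2.0 * m)) * z, n=m) * m
    return w[:n]


# ---------------------------------------------------------------------------
# H-tree builders
# ---------------------------------------------------------------------------

def _child_directions(u: np.ndarray, n: np.ndarray, phi_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Sibling directions at a fork: parent axis rotated ±phi about the plane normal."""
    phi = np.deg2rad(phi_deg)
    w = np.cross(n, u)
    d_plus = u * np.cos(phi) + w * np.sin(phi)
    d_minus = u * np.cos(phi) - w * np.sin(phi)
    return _geom.unit(d_plus), _geom.unit(d_minus)


def _build_binary_tree(
    lengths: np.ndarray,
    width: float,
    phi_deg: float,
    three_d: bool,
    weave_sigma: float,
    hurst: float,
    segment_length: float,
    rng: np.random.Generator | None,
    plane_rotation_deg: float | None = None,
) -> CenterlineArbor:
    radius = width / 2.0
    nodes: list[CenterlineNode] = [CenterlineNode(0, np.zeros(3), radius, None, SOMA)]
    next_id = 1

    def add_node(pos, parent):
        nonlocal next_id
        nodes.append(CenterlineNode(next_id, pos, radius, parent))
        next_id += 1
        return next_id - 1

    def grow_branch(start_pos, parent_node, u, level):
        """Grow one branch; returns (tip position, tip node id, tip direction)."""
        L = lengths[level - 1]
        if weave_sigma > 0:
            m = max(2, int(round(L / segment_length)))
            seg_len = L / m
            angles = fractional_gaussian_noise(m - 1, hurst, rng)
            s = angles.std()
            angles = angles * (weave_sigma / s) if s > 0 else np.zeros(m - 1)
            pos, nid, v = np.asarray(start_pos, float), parent_node, np.asarray(u, float)
            e1 = _geom.perpendicular_vector(v)
            for j in range(m):
                pos = pos + v * seg_len
                nid = add_node(pos, nid)
                if j < m - 1:
                    if three_d:
                        psi = rng.uniform(0.0, 2.0 * np.pi)
                        e2 = np.cross(v, e1)
                        axis = np.cos(psi) * e1 + np.sin(psi) * e2
                    else:
                        axis = np.array([0.0, 0.0, 1.0])
                    R = _geom.rotation_about_axis(axis, np.deg2rad(angles[j]))
                    v_new = _geom.unit(R @ v)
                    # transport the azimuth frame
                    e1 = _geom.minimal_rotation_to(v, v_new) @ e1
                    e1 = _geom.unit(e1 - v_new * np.dot(e1, v_new))
                    v = v_new
            return pos, nid, v
        tip = np.asarray(start_pos, float) + np.asarray(u, float) * L
        nid = add_node(tip, parent_node)
        return tip, nid, np.asarray(u, float)

    # iterative DFS; deterministic traversal order fixes the random stream
    u0 = np.array([1.0, 0.0, 0.0])
    n0 = np.array([0.0, 0.0, 1.0])
    stack = [(np.zeros(3), 0, u0, n0, 1)]
    while stack:
        start, parent, u, n, level = stack.pop()
        tip, tip_id, tip_dir = grow_branch(start, parent, u, level)
        if level < len(lengths):
            d1, d2 = _child_directions(tip_dir, n, phi_deg)
            for d_child in (d1, d2):
                if not three_d:
                    n_child = n
                elif plane_rotation_deg is None:
                    # classic 3D H-tree: branching plane flips 90° per level
                    n_child = tip_dir
                else:
                    # rotate the plane normal about the child axis; n ⟂ d_child
                    # holds by construction since both u and n×u are ⟂ n
                    R = _geom.rotation_about_axis(d_child, np.deg2rad(plane_rotation_deg))
                    n_child = _geom.unit(R @ n - d_child * np.dot(R @ n, d_child))
                stack.append((tip, tip_id, d_child, n_child, level + 1))
    return CenterlineArbor(nodes)


def generate_htree(spec: HTreeSpec) -> CenterlineArbor:
    """Straight H-tree following the level scaling law exactly.

    Level-i branch count is 2^(i-1); sibling branches fork at 90° to the
    parent axis (fork angle between siblings 180°, between child and
    parent 90°); 3D trees rotate the branching plane 90° per level.
    """
    if spec.weave_sigma != 0:
        raise ParameterError("use generate_weaving_htree for weave_sigma > 0")
    lengths = htree_level_lengths(spec)
    return _build_binary_tree(
        lengths, spec.width, 90.0, spec.dimensionality == "3D",
        0.0, spec.hurst, spec.width, None,
    )


def generate_weaving_htree(spec: HTreeSpec) -> CenterlineArbor:
    """H-tree whose branches weave with fGn-distributed angles.

    Branches are subdivided into segments (default length = branch width)
    and bent at each junction; arc length per branch is preserved, so the
    total wire length still matches the straight tree.  With
    ``weave_sigma == 0`` this is exactly :func:`generate_htree`.
    """
    if spec.weave_sigma == 0:
        return generate_htree(spec)
    lengths = htree_level_lengths(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 0x48545245]))
    seg_len = spec.segment_length if spec.segment_length is not None else spec.width
    return _build_binary_tree(
        lengths, spec.width, 90.0, spec.dimensionality == "3D",
        spec.weave_sigma, spec.hurst, seg_len, rng,
    )


def generate_equal_length_htree(
    phi: float,
    levels: int,
    branch_length: float | None = None,
    total_length: float | None = None,
    width: float = 1.0,
    dimensionality: Literal["2D", "3D"] = "3D",
) -> CenterlineArbor:
    """H-tree-like binary tree with all branch lengths equal and fork angle ``phi``.

    With ``phi = 90`` and enough levels the structure packs space densely
    (the non-fractal D → 3 limit); with the neurons' median ``phi = 37°``
    it retains limited-range fractal scaling.

    Because equal-length branches on the classic 90°-plane-rotation rule
    retrace a cubic lattice exactly (collapsing thousands of branches
    onto a few grid lines), the 3D branching plane is advanced by the
    golden angle per level here, which keeps the branches spread through
    the volume.
    """
    if not (0.0 < phi <= 180.0):
        raise ParameterError("phi must lie in (0°, 180°]")
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    if (branch_length is None) == (total_length is None):
        raise ParameterError("specify exactly one of branch_length or total_length")
    n_branches = 2 ** levels - 1
    ell = branch_length if branch_length is not None else total_length / n_branches
    lengths = np.full(levels, ell)
    return _build_binary_tree(
        lengths, width, phi, dimensionality == "3D", 0.0, 0.75, width, None,
        plane_rotation_deg=np.degrees(_GOLDEN_ANGLE_RAD),
    )


def equalize_htree(arbor: CenterlineArbor) -> CenterlineArbor:
    """Equalize an existing tree's branch lengths, preserving total length."""
    from .morphometry import equalize_branch_lengths

    return equalize_branch_lengths(arbor, preserve_total=True)


# ---------------------------------------------------------------------------
# Toy neuron-like arbors
# ---------------------------------------------------------------------------

def _half_normal(rng, median, size=None):
    # |N(0, s)| has median s * 0.6745
    return np.abs(rng.normal(0.0, median / 0.6744897501960817, size))


def _log_normal(rng, median, sigma=0.4, size=None):
    return np.exp(rng.normal(np.log(median), sigma, size))


def generate_toy_arbor(spec: ToyArborSpec) -> CenterlineArbor:
    """Random neuron-like arbor with the requested median morphometrics.

    The tree starts with ``n_primary`` branches at the soma; each branch
    is a chain of log-normal-length segments bent by half-normal weave
    angles in uniformly random azimuthal planes, and forks into two
    children (half-normal fork angles) until ``n_levels`` is reached.
    Sampled medians land within ~10% of the requested values for large trees.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 0x544F59]))
    nodes: list[CenterlineNode] = [CenterlineNode(0, np.zeros(3), spec.width_median, None, SOMA)]
    next_id = 1

    def add_node(pos, parent, radius):
        nonlocal next_id
        nodes.append(CenterlineNode(next_id, pos, radius, parent))
        next_id += 1
        return next_id - 1

    def grow(start, parent, v, level):
        radius = max(_log_normal(rng, spec.width_median), 0.2) / 2.0
        n_seg = max(2, int(round(_log_normal(rng, spec.segments_per_branch_median, 0.35))))
        e1 = _geom.perpendicular_vector(v)
        pos = np.asarray(start, float)
        nid = parent
        for j in range(n_seg):
            pos = pos + v * _log_normal(rng, spec.segment_length_median)
            nid = add_node(pos, nid, radius)
            if j < n_seg - 1:
                theta = _half_normal(rng, spec.theta_median)
                psi = rng.uniform(0, 2 * np.pi)
                e2 = np.cross(v, e1)
                axis = np.cos(psi) * e1 + np.sin(psi) * e2
                R = _geom.rotation_about_axis(axis, np.deg2rad(theta))
                v_new = _geom.unit(R @ v)
                e1 = _geom.minimal_rotation_to(v, v_new) @ e1
                e1 = _geom.unit(e1 - v_new * np.dot(e1, v_new))
                v = v_new
        if level < spec.n_levels and rng.uniform() < spec.fork_probability:
            psi0 = rng.uniform(0, 2 * np.pi)
            for s, dpsi in ((+1, 0.0), (-1, np.pi + rng.normal(0, 0.3))):
                phi = _half_normal(rng, spec.phi_median)
                psi = psi0 + dpsi
                e2 = np.cross(v, e1)
                axis = np.cos(psi) * e1 + np.sin(psi) * e2
                R = _geom.rotation_about_axis(axis, s * np.deg2rad(phi))
                grow(pos, nid, _geom.unit(R @ v), level + 1)

    # primary branches spread around the soma
    for p in range(spec.n_primary):
        z = rng.uniform(-1, 1)
        az = rng.uniform(0, 2 * np.pi)
        r = np.sqrt(1 - z * z)
        grow(np.zeros(3), 0, np.array([r * np.cos(az), r * np.sin(az), z]), 1)
    return CenterlineArbor(nodes)


# ---------------------------------------------------------------------------
# Euclidean fixtures
# ---------------------------------------------------------------------------

def generate_sphere_mesh(radius: float, refinement: int = 4) -> TriangleMesh:
    """Closed icosphere; area → 4πr² and volume → (4/3)πr³ with refinement."""
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    tm = _trimesh.creation.icosphere(subdivisions=refinement, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))


def generate_cube_mesh(side: float) -> TriangleMesh:
    if side <= 0:
        raise ParameterError("side must be > 0")
    tm = _trimesh.creation.box(extents=(side, side, side))
    return TriangleMesh(np.asarray(tm.vertices, float) + side / 2.0, np.asarray(tm.faces))


def generate_line_arbor(length: float, width: float = 1.0, n_nodes: int = 2) -> CenterlineArbor:
    """A single straight branch along +x — the D = 1 fixture."""
    if length <= 0 or width <= 0 or n_nodes < 2:
        raise ParameterError("need length > 0, width > 0, n_nodes >= 2")
    xs = np.linspace(0.0, length, n_nodes)
    nodes = [CenterlineNode(0, np.zeros(3), width / 2, None, SOMA)]
    nodes += [
        CenterlineNode(i, np.array([x, 0.0, 0.0]), width / 2, i - 1)
        for i, x in enumerate(xs[1:], start=1)
    ]
    return CenterlineArbor(nodes)
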