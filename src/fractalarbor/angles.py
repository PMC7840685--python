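"""Distorted arbor variants: multiply weave/fork angles by a factor α.

Junctions are processed from the angles furthest from the soma inwards.
At each junction the whole downstream subtree is rigidly rotated in the
plane of the two direction vectors defining the angle, so that the
junction angle θ becomes α·θ.  Because the subtree rotation is rigid,
segment lengths and every other downstream angle are untouched.  Angles
do not distinguish left from right of the local axis, so results are
always measured in [0°, 180°]: scaled angles beyond 180° fold back as
360° − α·θ (e.g. α = 2 applied to a 100° fork measures 160°).  Branches
may self-intersect after scaling; that is tolerated (it is rare below
α = 2) and can be counted with :func:`count_self_intersections`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from . import _geom
from .arbor import CenterlineArbor, CenterlineNode
from .errors import ParameterError

__all__ = [
    "ManipulationSpec",
    "ManipulationReport",
    "fold_angle",
    "scale_angles",
    "generate_variant_set",
    "count_self_intersections",
]

_EPS_DEG = 1e-9


@dataclass(frozen=True)
class ManipulationSpec:
    """α multiplier in [0, 2] applied to weave and/or fork angles."""

    alpha: float
    target: Literal["weave", "fork", "both"] = "weave"

    def __post_init__(self):
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if self.alpha > 2:
            raise ParameterError("alpha must be <= 2")
        if self.target not in ("weave", "fork", "both"):
            raise ParameterError("target must be weave, fork or both")


@dataclass
class ManipulationReport:
    """Bookkeeping of one scaling pass."""

    n_junctions: int = 0
    n_folded: int = 0          #: angles whose α·θ exceeded 180° (crossed the axis)
    n_skipped_degenerate: int = 0

    @property
    def folded_fraction(self) -> float:
        return self.n_folded / self.n_junctions if self.n_junctions else 0.0


def fold_angle(raw: float) -> float:
    """Fold a non-negative angle into [0°, 180°] (360° − raw above 180°)."""
    if raw < 0:
        raise ParameterError("angle must be >= 0")
    if raw > 360.0:
        warnings.warn(f"angle {raw}° exceeds 360°; folding modulo 360°")
        raw = raw % 360.0
    return raw if raw <= 180.0 else 360.0 - raw


def scale_angles(
    arbor: CenterlineArbor,
    spec: ManipulationSpec,
    return_report: bool = False,
) -> CenterlineArbor | tuple[CenterlineArbor, ManipulationReport]:
    """Multiply the selected angle population by ``spec.alpha``.

    Returns a new arbor; the input is unmodified.  With ``alpha == 1``
    the output coordinates equal the input's.  Junctions whose defining
    vectors are (anti)parallel have no rotation plane and are skipped
    (0° and 180° are fixed points of the multiplication).
    """
    alpha = spec.alpha
    report = ManipulationReport()
    branches = arbor.branches

    # Working from the angles furthest from the soma inwards, each rotation
    # is applied while its junction's pivot, axis and angle still sit at
    # their ORIGINAL coordinates (only junctions further out have acted, and
    # those move strictly downstream geometry).  The net map of a node is
    # therefore the composition of its ancestor junctions' original-frame
    # rotations, innermost applied last — which we evaluate in one pass
    # down the tree with an accumulated affine transform per node.
    #
    # Each junction is attached to the tree edge it bends:
    #   weave: edge (chain[k+1] -> chain[k+2]) inside a branch
    #   fork:  edge (anchor -> first node) of a non-soma-emanating branch
    junction_of_edge: dict[int, tuple[np.ndarray, np.ndarray]] = {}  # child id -> (u, pivot)
    if spec.target in ("weave", "both"):
        for b in branches:
            chain = b.node_ids
            for k in range(len(b.segments) - 1):
                u = b.segments[k].direction
                junction_of_edge[chain[k + 2]] = (u, arbor.nodes[chain[k + 1]].position)
    if spec.target in ("fork", "both"):
        for b in branches:
            if b.parent_branch is None:
                continue
            u = branches[b.parent_branch].segments[-1].direction
            junction_of_edge[b.node_ids[1]] = (u, arbor.nodes[b.node_ids[0]].position)

    ids = list(arbor.nodes)
    row = {nid: i for i, nid in enumerate(ids)}
    orig = np.array([arbor.nodes[nid].position for nid in ids])

    # per-node accumulated affine (R, t); children extend the parent's
    Rs = np.tile(np.eye(3), (len(ids), 1, 1))
    ts = np.zeros((len(ids), 3))
    order: list[int] = list(arbor.root_ids)
    seen = set(order)
    qi = 0
    while qi < len(order):
        nid = order[qi]
        qi += 1
        for child in arbor.children[nid]:
            if child in seen:
                continue
            seen.add(child)
            order.append(child)
            i_p, i_c = row[nid], row[child]
            R_acc, t_acc = Rs[i_p], ts[i_p]
            jn = junction_of_edge.get(child)
            if jn is not None:
                u, pivot = jn
                v = orig[i_c] - pivot
                report.n_junctions += 1
                vn = v / np.linalg.norm(v)
                c = float(np.clip(np.dot(u, vn), -1.0, 1.0))
                theta = np.degrees(np.arccos(c))
                if theta < _EPS_DEG or theta > 180.0 - _EPS_DEG:
                    report.n_skipped_degenerate += 1
                else:
                    if alpha * theta > 180.0:
                        report.n_folded += 1
                    delta = np.deg2rad((alpha - 1.0) * theta)
                    if abs(delta) >= 1e-15:
                        axis = np.cross(u, vn)
                        axis /= np.linalg.norm(axis)
                        M = _geom.rotation_about_axis(axis, delta)
                        # junction map J: x -> pivot + M (x - pivot),
                        # composed inside the accumulated transform
                        R_acc = R_acc @ M
                        t_acc = Rs[i_p] @ (pivot - M @ pivot) + t_acc
            Rs[i_c] = R_acc
            ts[i_c] = t_acc

    new_pos = np.einsum("nij,nj->ni", Rs, orig) + ts
    nodes = [
        CenterlineNode(nid, new_pos[row[nid]], arbor.nodes[nid].radius,
                       arbor.nodes[nid].parent_id, arbor.nodes[nid].kind)
        for nid in ids
    ]
    out = CenterlineArbor(nodes)
    return (out, report) if return_report else out


def generate_variant_set(
    arbor: CenterlineArbor,
    alphas: list[float],
    targets: list[str],
) -> list[tuple[ManipulationSpec, CenterlineArbor]]:
    """All |alphas| × |targets| variants, each derived from the input arbor."""
    out = []
    for target in targets:
        for alpha in alphas:
            spec = ManipulationSpec(alpha=alpha, target=target)
            out.append((spec, scale_angles(arbor, spec)))
    return out


def count_self_intersections(arbor: CenterlineArbor, tol: float = 0.0) -> int:
    """Number of non-adjacent segment pairs whose tubes overlap.

    Two segments intersect when the distance between their axes is below
    the sum of their radii; segments sharing an endpoint are skipped.
    """
    starts, ends, radii = arbor.segment_arrays()
    n = len(starts)
    if n < 2:
        return 0
    mids = 0.5 * (starts + ends)
    half = 0.5 * np.linalg.norm(ends - starts, axis=1)
    reach = half + radii
    tree = cKDTree(mids)
    pairs = tree.query_pairs(2.0 * reach.max(), output_type="ndarray")
    if not len(pairs):
        return 0
    i, j = pairs.T
    close = np.linalg.norm(mids[i] - mids[j], axis=1) <= reach[i] + reach[j]
    i, j = i[close], j[close]
    count = 0
    for a, b in zip(i, j):
        if _segments_adjacent(starts, ends, a, b):
            continue
        d = _segment_segment_distance(starts[a], ends[a], starts[b], ends[b])
        if d < radii[a] + radii[b] - tol:
            count += 1
    return count


def _segments_adjacent(starts, ends, a, b, eps=1e-9) -> bool:
    for p in (starts[a], ends[a]):
        for q in (starts[b], ends[b]):
            if np.linalg.norm(p - q) < eps:
                return True
    return False


def _segment_segment_distance(p1, p2, q1, q2) -> float:
    """Minimal distance between two 3-D segments (standard clamped form)."""
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    c = float(d1 @ r)
    b = float(d1 @ d2)
    den = a * e - b * b
    s = np.clip((b * f - c * e) / den, 0.0, 1.0) if den > 1e-15 else 0.0
    t = (b * s + f) / e if e > 1e-15 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-15 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-15 else 0.0
    return float(np.linalg.norm(p1 + d1 * s - (q1 + d2 * t)))
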