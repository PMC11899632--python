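"""Separating-axis intersection testing and pruning of swept rectangles.

On tightly curved paths consecutive cross-sections can cross each other,
which would fold the skinned surface.  Each pair of placed rectangles is
tested with the separating-axis theorem (SAT); rectangles are then removed
greedily, worst offender first, until no intersections remain.

The candidate axes are the two face normals, the pairwise cross products of
the edge directions, and — required for exactness when the two rectangles
are coplanar — the in-plane edge normals n × e of both rectangles.  Two
convex planar quadrilaterals are disjoint iff some axis in this set
separates their corner projections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError
from .sweep_engine import PlacedRectangle

log = logging.getLogger(__name__)

#: Projection intervals must overlap by more than this (mm) on every axis for
#: a pair to count as intersecting; grazing contact is not an intersection.
OVERLAP_TOLERANCE_MM = 1e-9

#: Rectangles this close in path order share skinning adjacency and touch by
#: construction; they are exempt from pruning.
ADJACENCY_EXEMPTION = 1


@dataclass
class IntersectionReport:
    """Outcome of pruning: intersecting pairs found, removal order, survivors."""

    pairs: list = field(default_factory=list)
    removed: list = field(default_factory=list)
    survivors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "intersecting_pairs": [list(p) for p in self.pairs],
            "removed": list(self.removed),
            "survivors": list(self.survivors),
        }


def _corners_of(rect) -> np.ndarray:
    if isinstance(rect, PlacedRectangle):
        return rect.corners
    return np.asarray(rect, dtype=float).reshape(4, 3)


def _axes(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    ea = np.diff(np.vstack([ca, ca[:1]]), axis=0)  # 4 true edges
    eb = np.diff(np.vstack([cb, cb[:1]]), axis=0)
    na = np.cross(ca[1] - ca[0], ca[3] - ca[0])
    nb = np.cross(cb[1] - cb[0], cb[3] - cb[0])
    if np.linalg.norm(na) < 1e-12 or np.linalg.norm(nb) < 1e-12:
        raise DegenerateGeometryError("zero-area rectangle in SAT test")
    cross = np.cross(ea[:, None, :], eb[None, :, :]).reshape(-1, 3)
    in_plane_a = np.cross(na, ea)
    in_plane_b = np.cross(nb, eb)
    axes = np.vstack([na[None, :], nb[None, :], cross, in_plane_a, in_plane_b])
    lens = np.linalg.norm(axes, axis=1)
    good = lens > 1e-12
    return axes[good] / lens[good, None]


def rectangles_intersect(
    a, b, tol: float = OVERLAP_TOLERANCE_MM
) -> bool:
    """SAT verdict for two planar rectangles in 3D.

    True iff the corner projections overlap by more than ``tol`` on every
    candidate axis (no separating axis exists).
    """
    ca, cb = _corners_of(a), _corners_of(b)
    for axis in _axes(ca, cb):
        pa = ca @ axis
        pb = cb @ axis
        gap = max(pa.min(), pb.min()) - min(pa.max(), pb.max())
        if gap > tol:
            return False  # clearly disjoint on this axis
        width = min(pa.max() - pa.min(), pb.max() - pb.min())
        # grazing contact only counts as separation on axes where both
        # rectangles have real extent; a rectangle's own normal axis always
        # projects it to a point and must not discard transversal crossings
        if gap > -tol and width > tol:
            return False
    return True


def _aabb_disjoint(ca: np.ndarray, cb: np.ndarray, pad: float) -> bool:
    return bool(
        (ca.max(axis=0) < cb.min(axis=0) - pad).any()
        or (cb.max(axis=0) < ca.min(axis=0) - pad).any()
    )


def find_intersections(
    rects: list, adjacency_exemption: int = ADJACENCY_EXEMPTION
) -> list[tuple[int, int]]:
    """All intersecting index pairs with |i − j| > ``adjacency_exemption``."""
    corners = [_corners_of(r) for r in rects]
    pairs = []
    n = len(corners)
    for i in range(n):
        for j in range(i + adjacency_exemption + 1, n):
            if _aabb_disjoint(corners[i], corners[j], OVERLAP_TOLERANCE_MM):
                continue
            if rectangles_intersect(corners[i], corners[j]):
                pairs.append((i, j))
    return pairs


def prune(
    rects: list, adjacency_exemption: int = ADJACENCY_EXEMPTION
) -> IntersectionReport:
    """Iteratively remove the rectangle intersecting the most others.

    Ties break toward the lowest index for determinism.  Because removing a
    rectangle never creates new intersections, the intersection graph is
    built once and nodes are deleted from it.
    """
    if len(rects) == 0:
        raise DegenerateGeometryError("prune needs at least 1 rectangle")
    pairs = find_intersections(rects, adjacency_exemption)
    neighbors: dict[int, set[int]] = {i: set() for i in range(len(rects))}
    for i, j in pairs:
        neighbors[i].add(j)
        neighbors[j].add(i)
    removed: list[int] = []
    while True:
        degrees = {i: len(v) for i, v in neighbors.items() if v}
        if not degrees:
            break
        top = max(degrees.values())
        worst = min(i for i, d in degrees.items() if d == top)
        removed.append(worst)
        for other in neighbors.pop(worst):
            neighbors[other].discard(worst)
    survivors = sorted(neighbors)
    if removed:
        log.info("pruned %d intersecting rectangles: %s", len(removed), removed)
    return IntersectionReport(pairs=pairs, removed=removed, survivors=survivors)
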