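"""Boolean subtraction of hole solids from the plate surface.

The subtraction follows the classical surface-Boolean recipe: compute the
intersection segments between the two triangulations (the "intersection
loops"), co-refine each surface so the loops become mesh edges, classify
every refined facet as inside or outside the other solid by its
generalized winding number, and stitch the kept facets — plate facets
outside the hole, hole facets inside the plate with reversed orientation —
into one watertight surface.

Per-triangle retriangulation happens in the triangle's own 2D plane using
shapely: the constraint segments are merged into chains, chains are
extended a hair past the triangle boundary and used to split the triangle
polygon; closed loops (a hole boundary entirely inside one facet) are
handled by polygon difference.  Each resulting face, possibly with holes,
is ear-clipped after bridging its interior rings to the shell.

Intersection-segment endpoints for a given triangle/edge are produced by
identical arithmetic on both meshes, so the refined boundaries conform and
a final vertex weld restores watertightness.
"""

from __future__ import annotations

import logging

import numpy as np
from shapely import LineString, MultiLineString, Polygon, line_merge
from shapely.ops import split as shapely_split

from .errors import BooleanError
from .mesh_io import TriangleMesh, diagnose, merge_duplicate_vertices

log = logging.getLogger(__name__)

_EPS_DIST = 1e-12      # signed-distance tolerance for plane classification
_EPS_SEG = 1e-10       # minimum intersection-segment length, mm
_EPS_EXT = 1e-6        # chain extension past the triangle boundary, mm
_WELD_TOL = 1e-9       # final vertex weld tolerance, mm
_MIN_AREA = 1e-14      # discard arrangement faces below this area, mm^2


# ---------------------------------------------------------------------------
# Triangle–triangle intersection
# ---------------------------------------------------------------------------

def _plane_crossings(tri: np.ndarray, d: np.ndarray) -> np.ndarray | None:
    """Points where ``tri``'s boundary crosses the plane with signed dists ``d``.

    Returns a (2, 3) array, or None when the triangle does not properly
    cross (all on one side, a single touching vertex, or coplanar contact).
    """
    sign = np.where(d > _EPS_DIST, 1, np.where(d < -_EPS_DIST, -1, 0))
    n_pos = int((sign > 0).sum())
    n_neg = int((sign < 0).sum())
    n_zero = 3 - n_pos - n_neg
    # transversal crossing needs vertices strictly on both sides; >= 2 on-plane
    # vertices means coplanar or edge-on-plane tangency
    if n_pos == 0 or n_neg == 0 or n_zero >= 2:
        return None
    pts = []
    for i in range(3):
        if sign[i] == 0:
            pts.append(tri[i])
    for i in range(3):
        j = (i + 1) % 3
        if sign[i] * sign[j] < 0:
            t = d[i] / (d[i] - d[j])
            pts.append(tri[i] + t * (tri[j] - tri[i]))
    if len(pts) != 2:
        return None
    return np.array(pts)


def tri_tri_segment(t1: np.ndarray, t2: np.ndarray) -> np.ndarray | None:
    """Transversal intersection segment of two triangles, or None.

    Returns (2, 3) endpoints.  Coplanar overlap is reported as None: it is a
    tangential, not transversal, contact and contributes no intersection
    loop.
    """
    t1 = np.asarray(t1, dtype=float).reshape(3, 3)
    t2 = np.asarray(t2, dtype=float).reshape(3, 3)
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    d1 = (t1 - t2[0]) @ n2 / np.linalg.norm(n2)
    d2 = (t2 - t1[0]) @ n1 / np.linalg.norm(n1)
    q1 = _plane_crossings(t1, d1)
    q2 = _plane_crossings(t2, d2)
    if q1 is None or q2 is None:
        return None
    axis = np.cross(n1, n2)
    norm = np.linalg.norm(axis)
    if norm < 1e-14:
        return None
    axis = axis / norm
    s1 = q1 @ axis
    s2 = q2 @ axis
    pts = np.vstack([q1, q2])
    svals = np.concatenate([s1, s2])
    lo = max(s1.min(), s2.min())
    hi = min(s1.max(), s2.max())
    if hi - lo <= _EPS_SEG:
        return None
    # pick the actual 3D points achieving the clipped interval bounds so that
    # neighbouring triangle pairs share endpoints bitwise
    p_lo = pts[np.argmin(np.abs(svals - lo))]
    p_hi = pts[np.argmin(np.abs(svals - hi))]
    return np.array([p_lo, p_hi])


def _to_2d_frame(tri: np.ndarray):
    origin = tri[0]
    ex = tri[1] - tri[0]
    ex = ex / np.linalg.norm(ex)
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    n = n / np.linalg.norm(n)
    ey = np.cross(n, ex)
    return origin, ex, ey


def tri_tri_overlap(t1: np.ndarray, t2: np.ndarray) -> bool:
    """True iff the triangles share area or a transversal segment.

    Used as the independent intersection oracle: transversal contact comes
    from the segment computation; coplanar contact falls back to a 2D
    polygon overlap test.
    """
    t1 = np.asarray(t1, dtype=float).reshape(3, 3)
    t2 = np.asarray(t2, dtype=float).reshape(3, 3)
    if tri_tri_segment(t1, t2) is not None:
        return True
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    d2 = (t2 - t1[0]) @ n1 / np.linalg.norm(n1)
    if np.abs(d2).max() < 1e-9:  # coplanar: overlap in the shared plane?
        origin, ex, ey = _to_2d_frame(t1)
        p1 = Polygon((t1 - origin) @ np.stack([ex, ey], axis=1))
        p2 = Polygon((t2 - origin) @ np.stack([ex, ey], axis=1))
        return bool(p1.intersection(p2).area > 1e-12)
    return False


# ---------------------------------------------------------------------------
# Polygon triangulation (ear clipping, holes via bridging)
# ---------------------------------------------------------------------------

def _ring_coords(ring, ccw: bool) -> list[tuple[float, float]]:
    coords = list(ring.coords[:-1])
    area = 0.0
    for (x0, y0), (x1, y1) in zip(coords, coords[1:] + coords[:1]):
        area += x0 * y1 - x1 * y0
    if (area > 0) != ccw:
        coords.reverse()
    return coords


def _point_in_tri_2d(p, a, b, c, eps=1e-14) -> bool:
    d1 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    d2 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
    d3 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
    return d1 >= -eps and d2 >= -eps and d3 >= -eps


def _earclip(coords: list[tuple[float, float]]) -> list[tuple]:
    """Triangulate a simple CCW polygon (tolerates bridge double-edges)."""
    n = len(coords)
    if n < 3:
        return []
    idx = list(range(n))
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 4 * n * n:
        guard += 1
        ear_found = False
        for k in range(len(idx)):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % len(idx)]
            a, b, c = coords[i0], coords[i1], coords[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 0:
                continue  # reflex or degenerate corner
            contains = False
            for m in idx:
                if m in (i0, i1, i2):
                    continue
                if _point_in_tri_2d(coords[m], a, b, c, eps=-1e-14):
                    contains = True
                    break
            if contains:
                continue
            tris.append((a, b, c))
            idx.pop(k)
            ear_found = True
            break
        if not ear_found:
            # numerically stuck (collinear chains): drop the flattest corner
            flattest = min(
                range(len(idx)),
                key=lambda k: abs(
                    (coords[idx[k]][0] - coords[idx[k - 1]][0])
                    * (coords[idx[(k + 1) % len(idx)]][1] - coords[idx[k - 1]][1])
                    - (coords[idx[k]][1] - coords[idx[k - 1]][1])
                    * (coords[idx[(k + 1) % len(idx)]][0] - coords[idx[k - 1]][0])
                ),
            )
            idx.pop(flattest)
    if len(idx) == 3:
        a, b, c = (coords[i] for i in idx)
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if cross > 0:
            tris.append((a, b, c))
    return tris


def _bridge_holes(poly: Polygon) -> list[tuple[float, float]]:
    """Merge interior rings into the shell with mutually visible bridges."""
    shell = _ring_coords(poly.exterior, ccw=True)
    for ring in poly.interiors:
        hole = _ring_coords(ring, ccw=False)
        bridged = False
        for hi, hp in enumerate(hole):
            for si, sp in enumerate(shell):
                seg = LineString([hp, sp])
                if poly.covers(seg):
                    shell = (
                        shell[: si + 1]
                        + hole[hi:]
                        + hole[: hi + 1]
                        + shell[si:]
                    )
                    bridged = True
                    break
            if bridged:
                break
        if not bridged:
            raise BooleanError("could not bridge an interior ring for triangulation")
    return shell


def triangulate_polygon_2d(poly: Polygon) -> list[tuple]:
    if poly.is_empty or poly.area < _MIN_AREA:
        return []
    coords = _bridge_holes(poly) if poly.interiors else _ring_coords(poly.exterior, ccw=True)
    return _earclip(coords)


# ---------------------------------------------------------------------------
# Co-refinement
# ---------------------------------------------------------------------------

def _retriangulate_face(tri: np.ndarray, segments: list[np.ndarray]) -> np.ndarray:
    """Split one 3D triangle by its constraint segments; returns (k, 3, 3)."""
    origin, ex, ey = _to_2d_frame(tri)
    basis = np.stack([ex, ey], axis=1)

    def to2d(p):
        return (np.asarray(p) - origin) @ basis

    def to3d(xy):
        return origin + xy[0] * ex + xy[1] * ey

    tri2d = to2d(tri)
    merged = line_merge(MultiLineString([[tuple(to2d(s[0])), tuple(to2d(s[1]))] for s in segments]))
    lines = [merged] if isinstance(merged, LineString) else list(merged.geoms)

    pieces = [Polygon(tri2d)]
    for line in lines:
        coords = np.asarray(line.coords)
        if np.allclose(coords[0], coords[-1], atol=1e-12) and len(coords) > 3:
            inner = Polygon(coords)  # closed loop strictly inside the facet
            new_pieces = []
            for p in pieces:
                for g in (p.difference(inner), p.intersection(inner)):
                    new_pieces.extend(
                        q for q in getattr(g, "geoms", [g])
                        if isinstance(q, Polygon) and q.area > _MIN_AREA
                    )
            pieces = new_pieces
            continue
        d0 = coords[0] - coords[1]
        d1 = coords[-1] - coords[-2]
        d0 = d0 / max(np.linalg.norm(d0), 1e-30)
        d1 = d1 / max(np.linalg.norm(d1), 1e-30)
        extended = LineString(
            np.vstack([coords[0] + _EPS_EXT * d0, coords, coords[-1] + _EPS_EXT * d1])
        )
        new_pieces = []
        for p in pieces:
            result = shapely_split(p, extended)
            new_pieces.extend(
                q for q in result.geoms if isinstance(q, Polygon) and q.area > _MIN_AREA
            )
        pieces = new_pieces

    out = []
    for p in pieces:
        for a, b, c in triangulate_polygon_2d(p):
            out.append([to3d(a), to3d(b), to3d(c)])
    if not out:
        raise BooleanError("retriangulation produced no faces")
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Winding-number classification
# ---------------------------------------------------------------------------

def winding_numbers(points: np.ndarray, mesh: TriangleMesh, chunk: int = 256) -> np.ndarray:
    """Generalized winding number of ``mesh`` at each query point.

    ~1 inside a closed outward-oriented surface, ~0 outside (van Oosterom's
    solid-angle formula, summed over facets).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.triangles
    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        p = points[start : start + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("pmi,pmi->pm", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pmi,pmi->pm", a, b) * lc
            + np.einsum("pmi,pmi->pm", b, c) * la
            + np.einsum("pmi,pmi->pm", c, a) * lb
        )
        out[start : start + chunk] = np.arctan2(det, denom).sum(axis=1) / (2.0 * np.pi)
    return out


# ---------------------------------------------------------------------------
# Subtraction
# ---------------------------------------------------------------------------

def _snap_endpoints(segments: list[np.ndarray], tol: float = _WELD_TOL) -> None:
    """Weld intersection-segment endpoints in place.

    The same curve point is computed by several triangle pairs with
    different operand orderings, so coordinates agree only to rounding.
    Chain merging and retriangulation need them bitwise identical.
    """
    from scipy.spatial import cKDTree

    if not segments:
        return
    pts = np.concatenate(segments).reshape(-1, 3)
    n = len(pts)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(pts)
    for i, j in tree.query_pairs(tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    reps = np.array([find(i) for i in range(n)])
    snapped = pts[reps]
    for k, seg in enumerate(segments):
        seg[0] = snapped[2 * k]
        seg[1] = snapped[2 * k + 1]


def _candidate_pairs(a: TriangleMesh, b: TriangleMesh, pad: float = 1e-9) -> np.ndarray:
    ta, tb = a.triangles, b.triangles
    lo_a, hi_a = ta.min(axis=1), ta.max(axis=1)
    lo_b, hi_b = tb.min(axis=1), tb.max(axis=1)
    near = np.nonzero(
        ~((hi_a < lo_b.min(axis=0) - pad) | (lo_a > hi_b.max(axis=0) + pad)).any(axis=1)
    )[0]
    pairs = []
    for i in near:
        overlap = ~(
            (hi_a[i][None, :] < lo_b - pad) | (lo_a[i][None, :] > hi_b + pad)
        ).any(axis=1)
        for j in np.nonzero(overlap)[0]:
            pairs.append((i, j))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def _require_closed(mesh: TriangleMesh, name: str) -> None:
    diag = diagnose(mesh)
    if not (diag.is_watertight and diag.is_consistently_oriented):
        raise BooleanError(
            f"{name} is not a closed oriented surface "
            f"(watertight={diag.is_watertight}, oriented={diag.is_consistently_oriented})"
        )


def _subtract_one(a: TriangleMesh, b: TriangleMesh, label: str) -> TriangleMesh:
    pairs = _candidate_pairs(a, b)
    ta, tb = a.triangles, b.triangles
    segs_a: dict[int, list[np.ndarray]] = {}
    segs_b: dict[int, list[np.ndarray]] = {}
    all_segs: list[np.ndarray] = []
    for i, j in pairs:
        seg = tri_tri_segment(ta[i], tb[j])
        if seg is None:
            continue
        all_segs.append(seg)
        segs_a.setdefault(int(i), []).append(seg)
        segs_b.setdefault(int(j), []).append(seg)
    _snap_endpoints(all_segs)

    if not segs_a:
        if winding_numbers(a.vertices[:1], b)[0] > 0.5:
            raise BooleanError(f"plate lies entirely inside {label}")
        if winding_numbers(b.vertices[:1], a)[0] > 0.5:
            # disjoint surfaces, hole solid fully buried: cut an internal cavity
            flipped = TriangleMesh(b.vertices.copy(), b.faces[:, ::-1].copy())
            v = np.vstack([a.vertices, flipped.vertices])
            f = np.vstack([a.faces, flipped.faces + len(a.vertices)])
            return TriangleMesh(*merge_duplicate_vertices(v, f, _WELD_TOL))
        return a.copy()

    def refine(mesh: TriangleMesh, segs: dict[int, list[np.ndarray]]) -> np.ndarray:
        tris = mesh.triangles
        kept = [tris[i] for i in range(len(tris)) if i not in segs]
        refined = [_retriangulate_face(tris[i], s) for i, s in segs.items()]
        return np.concatenate([np.asarray(kept).reshape(-1, 3, 3)] + refined)

    fa = refine(a, segs_a)
    fb = refine(b, segs_b)

    ca = fa.mean(axis=1)
    cb = fb.mean(axis=1)
    keep_a = np.ones(len(fa), dtype=bool)
    lo_b = b.vertices.min(axis=0) - 1e-6
    hi_b = b.vertices.max(axis=0) + 1e-6
    near_b = ((ca >= lo_b) & (ca <= hi_b)).all(axis=1)
    keep_a[near_b] = winding_numbers(ca[near_b], b) < 0.5
    keep_b = winding_numbers(cb, a) > 0.5

    tris_out = np.concatenate([fa[keep_a], fb[keep_b][:, ::-1, :]])
    # collinear chain vertices can yield zero-area ear slivers; drop them and
    # let the T-junction pass restore conforming edges
    areas = 0.5 * np.linalg.norm(
        np.cross(tris_out[:, 1] - tris_out[:, 0], tris_out[:, 2] - tris_out[:, 0]), axis=1
    )
    tris_out = tris_out[areas > 1e-12]
    flat = tris_out.reshape(-1, 3)
    faces = np.arange(len(flat), dtype=np.int64).reshape(-1, 3)
    v, f = merge_duplicate_vertices(flat, faces, _WELD_TOL)
    f = _conform_t_junctions(v, f)
    out = TriangleMesh(v, f)
    out.validate()
    return out


def _conform_t_junctions(
    vertices: np.ndarray, faces: np.ndarray, tol: float = 10 * _WELD_TOL
) -> np.ndarray:
    """Split face edges that pass through other mesh vertices.

    Retriangulation can drop a vertex that lies exactly on a straight chord
    of the intersection curve (the 2D ear clipper sees a collinear corner),
    leaving a T-junction against the other mesh's conforming edge.  This
    pass restores shared edges by fanning any face whose edge contains
    other vertices in its interior.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(vertices)
    out: list[np.ndarray] = []
    stack = [tuple(face) for face in faces]
    while stack:
        i0, i1, i2 = stack.pop()
        tri_idx = (i0, i1, i2)
        split_done = False
        for e in range(3):
            a, b = tri_idx[e], tri_idx[(e + 1) % 3]
            c = tri_idx[(e + 2) % 3]
            pa, pb = vertices[a], vertices[b]
            mid = 0.5 * (pa + pb)
            half = 0.5 * np.linalg.norm(pb - pa)
            cand = tree.query_ball_point(mid, half + tol)
            d = pb - pa
            L2 = float(d @ d)
            hits = []
            for k in cand:
                if k in tri_idx:
                    continue
                t = float((vertices[k] - pa) @ d) / L2
                if not (1e-9 < t < 1 - 1e-9):
                    continue
                if np.linalg.norm(vertices[k] - (pa + t * d)) < tol:
                    hits.append((t, k))
            if hits:
                hits.sort()
                chain = [a] + [k for _, k in hits] + [b]
                for u, w in zip(chain[:-1], chain[1:]):
                    stack.append((u, w, c))
                split_done = True
                break
        if not split_done:
            out.append(np.array(tri_idx, dtype=np.int64))
    return np.asarray(out, dtype=np.int64).reshape(-1, 3)


def subtract(
    plate: TriangleMesh, holes: list[TriangleMesh], check_result: bool = True
) -> TriangleMesh:
    """Subtract every hole solid from the plate; result stays watertight.

    Preconditions: the plate and each hole are closed, consistently oriented
    surfaces and the holes are pairwise disjoint (so subtraction order
    cannot matter).  Holes that miss the plate entirely leave it unchanged.
    """
    _require_closed(plate, "plate")
    for idx, h in enumerate(holes):
        _require_closed(h, f"hole {idx}")
    for i in range(len(holes)):
        for j in range(i + 1, len(holes)):
            if len(_candidate_pairs(holes[i], holes[j])):
                for fi, fj in _candidate_pairs(holes[i], holes[j]):
                    if tri_tri_overlap(holes[i].triangles[fi], holes[j].triangles[fj]):
                        raise BooleanError(f"hole solids {i} and {j} intersect")
    result = plate
    for idx, h in enumerate(holes):
        try:
            result = _subtract_one(result, h, f"hole {idx}")
        except BooleanError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise BooleanError(f"Boolean subtraction failed on hole {idx}: {exc}") from exc
    if check_result and holes:
        diag = diagnose(result)
        if not (diag.is_watertight and diag.is_consistently_oriented):
            raise BooleanError(
                f"subtraction produced a non-watertight surface "
                f"(watertight={diag.is_watertight}, oriented={diag.is_consistently_oriented})"
            )
    return result
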