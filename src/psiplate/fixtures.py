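"""Synthetic inputs: a bone-like tube mesh, on-surface plans, statics cases.

Nothing here aspires to anatomical realism — the bone is a curved tube
(mandible-like horseshoe) with mild seeded surface jitter, the plan points
lie on its outer surface, and the statics cases are forward-constructed so
the planted reaction vectors are known exactly.  All generators are
deterministic for a given seed.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .mesh_io import TriangleMesh
from .statics_model import MuscleAction, ReactionGeometry, StaticsSolution
from .trace_curves import PlanPoints


def make_bone(
    length: float = 80.0,
    curvature_radius: float | None = 60.0,
    cross_radius: float = 6.0,
    seed: int = 0,
    n_rings: int = 60,
    n_around: int = 32,
    jitter: float = 0.08,
) -> TriangleMesh:
    """Watertight swept-tube mesh along a circular arc.

    ``curvature_radius=None`` gives a straight cylinder along +x.  Surface
    jitter (mm, radial) is seeded and small compared to ``cross_radius``.
    The generating parameters are kept in ``mesh.metadata`` so plan points
    can be laid on the analytic surface.
    """
    if length <= 0 or cross_radius <= 0:
        raise ParameterError("bone dimensions must be positive")
    rng = np.random.default_rng(seed)
    ts = np.linspace(0.0, 1.0, n_rings)
    phis = np.linspace(0.0, 2.0 * np.pi, n_around, endpoint=False)

    centers, tangents, radials = _arc_frames(ts, length, curvature_radius)
    verts = []
    for i in range(n_rings):
        binormal = np.cross(tangents[i], radials[i])
        for phi in phis:
            radial_dir = np.cos(phi) * radials[i] + np.sin(phi) * binormal
            r = cross_radius + jitter * rng.standard_normal()
            verts.append(centers[i] + r * radial_dir)
    start_center = centers[0].copy()
    end_center = centers[-1].copy()
    verts.extend([start_center, end_center])
    verts = np.asarray(verts)

    faces = []
    for i in range(n_rings - 1):
        a0, b0 = i * n_around, (i + 1) * n_around
        for j in range(n_around):
            k = (j + 1) % n_around
            faces.append((a0 + j, b0 + k, a0 + k))
            faces.append((a0 + j, b0 + j, b0 + k))
    ic_start, ic_end = len(verts) - 2, len(verts) - 1
    last0 = (n_rings - 1) * n_around
    for j in range(n_around):
        k = (j + 1) % n_around
        faces.append((ic_start, j, k))            # start cap faces −tangent
        faces.append((ic_end, last0 + k, last0 + j))  # end cap faces +tangent
    mesh = TriangleMesh(verts, np.array(faces, dtype=np.int64))
    if mesh.volume() < 0:  # orient outward regardless of frame handedness
        mesh.faces = mesh.faces[:, ::-1].copy()
    mesh.validate()
    mesh.metadata.update(
        length=length,
        curvature_radius=curvature_radius,
        cross_radius=cross_radius,
        seed=seed,
    )
    return mesh


def _arc_frames(ts: np.ndarray, length: float, curvature_radius: float | None):
    """Centerline points, tangents and outward radial directions."""
    if curvature_radius is None or not np.isfinite(curvature_radius):
        centers = np.stack([ts * length, np.zeros_like(ts), np.zeros_like(ts)], axis=1)
        tangents = np.tile([1.0, 0.0, 0.0], (len(ts), 1))
        radials = np.tile([0.0, -1.0, 0.0], (len(ts), 1))
        return centers, tangents, radials
    span = length / curvature_radius  # total arc angle
    theta = (ts - 0.5) * span
    centers = np.stack(
        [
            curvature_radius * np.sin(theta),
            curvature_radius * (1.0 - np.cos(theta)),
            np.zeros_like(theta),
        ],
        axis=1,
    )
    tangents = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    radials = np.stack([np.sin(theta), -np.cos(theta), np.zeros_like(theta)], axis=1)
    return centers, tangents, radials


def make_plan(
    bone: TriangleMesh,
    n_points: int = 8,
    n_holes: int = 3,
    seed: int = 0,
    span: float = 0.85,
    pick_jitter: float = 0.2,
) -> PlanPoints:
    """Surgeon-style picks on the outer bone surface.

    C1 runs along the tube's outer equator, C2 is the same arc shifted in
    poloidal angle (still on the surface), and P1 jitters a subset of the
    interior C1 picks by ``pick_jitter`` mm to exercise hole snapping.
    """
    if n_points < 2:
        raise ParameterError("need at least 2 plan points")
    if n_holes > max(n_points - 2, 0):
        raise ParameterError("n_holes must leave two hole-free end picks")
    meta = bone.metadata
    if "cross_radius" not in meta:
        raise ParameterError("bone mesh lacks generator metadata; use make_bone output")
    rng = np.random.default_rng(seed + 1)
    ts = 0.5 + (np.linspace(-0.5, 0.5, n_points) * span)
    centers, tangents, radials = _arc_frames(
        ts, meta["length"], meta["curvature_radius"]
    )
    r = meta["cross_radius"]
    c1 = centers + r * radials  # outer equator (z = 0 plane of the tube)
    poloidal = np.radians(35.0)
    c2 = []
    for i in range(n_points):
        binormal = np.cross(tangents[i], radials[i])
        direction = np.cos(poloidal) * radials[i] + np.sin(poloidal) * binormal
        c2.append(centers[i] + r * direction)
    c2 = np.asarray(c2)
    interior = np.arange(1, n_points - 1)
    hole_idx = interior[np.round(np.linspace(0, len(interior) - 1, n_holes)).astype(int)] \
        if n_holes else np.array([], dtype=int)
    p1 = c1[hole_idx] + pick_jitter * rng.standard_normal((len(hole_idx), 3))
    return PlanPoints(C1=c1, C2=c2, P1=p1)


# ---------------------------------------------------------------------------
# Statics
# ---------------------------------------------------------------------------

def synthetic_reaction_geometry() -> ReactionGeometry:
    """Plausible right-molar tooth point and condyle points (mm), with the
    standard angle assumptions."""
    return ReactionGeometry(
        tooth=[30.0, 10.0, 0.0],
        condyle_left=[-50.0, -35.0, 30.0],
        condyle_right=[50.0, -35.0, 30.0],
    )


def make_statics_case(
    seed: int = 0, n_random_muscles: int = 5
) -> tuple[list[MuscleAction], ReactionGeometry, StaticsSolution]:
    """Forward-constructed equilibrium problem with a known solution.

    Random non-degenerate geometry and angles are drawn; reaction vectors
    satisfying the three angle constraints are planted; then muscle actions
    are synthesized whose net wrench exactly balances the planted
    reactions (a point force plus a couple represent the residual wrench).
    """
    rng = np.random.default_rng(seed)
    while True:
        tooth = rng.uniform(-50, 50, 3)
        cl = rng.uniform(-50, 50, 3)
        cr = rng.uniform(-50, 50, 3)
        if np.linalg.norm(np.cross(cl - tooth, cr - tooth)) > 100.0:
            break
    alpha, beta = rng.uniform(20, 160, 2)
    gamma = rng.uniform(20, 160)
    geom = ReactionGeometry(
        tooth=tooth, condyle_left=cl, condyle_right=cr,
        alpha_deg=alpha, beta_deg=beta, gamma_deg=gamma,
    )
    al, be, ga = np.radians([alpha, beta, gamma])
    # T direction satisfying sinα·Ty = cosα·Tz and sinβ·Tx = cosβ·Tz
    t_dir = np.array([np.cos(be) * np.sin(al), np.cos(al) * np.sin(be),
                      np.sin(al) * np.sin(be)])
    T = rng.uniform(100, 400) * t_dir / np.linalg.norm(t_dir)
    CL = rng.uniform(50, 200) * _unit([np.cos(ga), 0.0, np.sin(ga)]) \
        + rng.uniform(-100, 100) * np.array([0.0, 1.0, 0.0])
    CR = rng.uniform(-150, 150, 3)

    muscles = [
        MuscleAction(f"RND{i}", rng.uniform(-80, 80, 3), rng.uniform(-50, 50, 3))
        for i in range(n_random_muscles)
    ]
    f_mus = np.sum([m.force for m in muscles], axis=0)
    m_mus = np.sum([np.cross(m.attachment, m.force) for m in muscles], axis=0)
    f_res = -(T + CL + CR + f_mus)       # force the extra muscles must supply
    m_res = -(
        np.cross(tooth, T) + np.cross(cl, CL) + np.cross(cr, CR) + m_mus
    )                                     # moment they must supply
    if np.linalg.norm(f_res) < 1e-9:
        f_res = np.array([1.0, 0.0, 0.0])  # keep the construction well posed
        muscles.append(MuscleAction("BAL0", -f_res, np.zeros(3)))
    # point force f_res placed so its moment matches the component of m_res
    # perpendicular to f_res; the parallel remainder becomes a couple
    f2 = float(f_res @ f_res)
    r_point = np.cross(f_res, m_res) / f2
    m_left = m_res - np.cross(r_point, f_res)
    muscles.append(MuscleAction("BALF", f_res, r_point))
    if np.linalg.norm(m_left) > 0:
        arm = _any_perp(m_left)
        f_c = np.cross(m_left, arm) / (arm @ arm)
        muscles.append(MuscleAction("CPL+", f_c, arm))
        muscles.append(MuscleAction("CPL-", -f_c, np.zeros(3)))
    planted = StaticsSolution(T=T, CL=CL, CR=CR)
    return muscles, geom, planted


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _any_perp(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) <= abs(v[1]) else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, helper)
    return p / np.linalg.norm(p)
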