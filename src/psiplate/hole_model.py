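"""Screw-hole placement along the path and countersunk hole meshes.

Hole centers are a subset of the sweep path: the surgeon's picks are
snapped to their nearest path sample, and one hole is auto-placed at each
end of the plate, half a boss diameter inside the terminus, so the plate
ends in a disc around it.  The cutting solid for each hole is a surface of
revolution — a cylindrical shaft of diameter φ topped by a conical
countersink opening to Ø at half-angle ß — built from stacked circles whose
peripheral points are triangulated, closed by fans at both ends, then
rotated onto the hole axis (the local plate-thickness direction) and
translated to the center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import HoleLayoutError, HoleSpecError
from .mesh_io import TriangleMesh
from .sweep_engine import HoleLayout, SweepFrame, _rodrigues, compute_frames
from .trace_curves import TraceCurvePair

log = logging.getLogger(__name__)


@dataclass
class HoleSpec:
    """Countersunk hole: shaft φ, head Ø, total height Ħ, head height ħ, angle ß.

    ß is the countersink half-angle from the hole axis, which ties the head
    height to the diameters: ħ = ((Ø − φ)/2) / tan ß.  ß wins when both are
    given and disagree.
    """

    shaft_diameter: float = 2.0
    head_diameter: float = 3.5
    height: float = 2.4
    head_height: float | None = None
    head_angle_deg: float = 45.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    segments: int = 64

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        if not self.head_diameter >= self.shaft_diameter > 0:
            raise HoleSpecError("need head diameter Ø >= shaft diameter φ > 0")
        if not 0 < self.head_angle_deg < 90:
            raise HoleSpecError("head angle ß must be in (0°, 90°)")
        if self.segments < 8:
            raise HoleSpecError("need at least 8 circle segments")
        n = np.linalg.norm(self.axis)
        if n < 1e-12:
            raise HoleSpecError("hole axis has zero length")
        self.axis = self.axis / n
        implied = self.implied_head_height()
        if self.head_height is None:
            self.head_height = implied
        elif abs(self.head_height - implied) > 1e-6:
            warnings.warn(
                f"head height ħ={self.head_height:.6g} mm inconsistent with "
                f"ß={self.head_angle_deg}° and diameters (implies ħ={implied:.6g} mm); "
                "using the angle",
                stacklevel=2,
            )
            self.head_height = implied
        if not self.height > self.head_height >= 0:
            raise HoleSpecError(
                f"need height Ħ > head height ħ >= 0 (Ħ={self.height}, ħ={self.head_height})"
            )

    def implied_head_height(self) -> float:
        half_span = (self.head_diameter - self.shaft_diameter) / 2.0
        return half_span / np.tan(np.radians(self.head_angle_deg))


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

@dataclass
class PlacedHole:
    """A hole center snapped onto the path with its cutting axis."""

    center: np.ndarray
    axis: np.ndarray
    path_index: int
    is_end_hole: bool = False


def _thickness_axis(frame: SweepFrame) -> np.ndarray:
    v = frame.tangent
    u = frame.angulation
    u_proj = u - (u @ v) * v
    w = u_proj / np.linalg.norm(u_proj)
    return np.cross(v, w)


def place_holes(
    P1: np.ndarray,
    curves: TraceCurvePair,
    layout: HoleLayout,
) -> tuple[list[PlacedHole], HoleLayout]:
    """Snap manual hole picks to the path and add the two end holes.

    End holes sit at arc length D/2 inside each terminus.  Each hole's axis
    is the local plate-thickness direction v̂ × ŵ.  Returns the holes in
    path order plus a copy of the layout carrying their centers (end holes
    first and last).
    """
    path = curves.path
    frames = compute_frames(curves)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    r = layout.boss_diameter / 2.0
    if arc[-1] <= 2 * r:
        raise HoleLayoutError(
            f"path length {arc[-1]:.3g} mm too short for end holes (needs > D = "
            f"{layout.boss_diameter:.3g} mm)"
        )
    i_first = int(np.argmin(np.abs(arc - r)))
    i_last = int(np.argmin(np.abs(arc - (arc[-1] - r))))

    holes = [PlacedHole(path[i_first], _thickness_axis(frames[i_first]), i_first, True)]
    P1 = np.asarray(P1, dtype=float).reshape(-1, 3)
    manual_idx = []
    for p in P1:
        i = int(np.argmin(np.linalg.norm(path - p, axis=1)))
        offset = float(np.linalg.norm(path[i] - p))
        if offset > 1e-9:
            log.info("hole pick %s snapped to path sample %d (offset %.3g mm)", p, i, offset)
        manual_idx.append(i)
    for i in sorted(manual_idx):
        holes.append(PlacedHole(path[i], _thickness_axis(frames[i]), i, False))
    holes.append(PlacedHole(path[i_last], _thickness_axis(frames[i_last]), i_last, True))

    centers = [h.center for h in holes]
    for a in range(len(centers) - 1):
        d = float(np.linalg.norm(centers[a] - centers[a + 1]))
        if d < layout.boss_diameter:
            raise HoleLayoutError(
                f"holes {a} and {a + 1} are {d:.3g} mm apart; bosses of diameter "
                f"{layout.boss_diameter:.3g} mm would merge"
            )
    placed_layout = HoleLayout(
        centers=centers,
        screw_diameter=layout.screw_diameter,
        boss_diameter=layout.boss_diameter,
    )
    return holes, placed_layout


# ---------------------------------------------------------------------------
# Hole mesh
# ---------------------------------------------------------------------------

def build_hole_mesh(spec: HoleSpec) -> TriangleMesh:
    """Watertight surface of revolution for one countersunk hole.

    The canonical solid is centered on its axis: shaft from z = −Ħ/2 to
    z = Ħ/2 − ħ, countersink cone to z = Ħ/2, fan caps at both ends; it is
    then rotated so +z maps to ``spec.axis`` and translated to the center.
    """
    rs = spec.shaft_diameter / 2.0
    rh = spec.head_diameter / 2.0
    z0, z1, z2 = -spec.height / 2.0, spec.height / 2.0 - spec.head_height, spec.height / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, spec.segments, endpoint=False)
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1)

    levels: list[tuple[float, float]] = [(z0, rs)]
    if spec.head_height > 0:
        levels += [(z1, rs), (z2, rh)]
    else:
        levels += [(z2, rs)]

    verts: list[np.ndarray] = []
    for z, r in levels:
        verts.append(np.column_stack([r * ring, np.full(spec.segments, z)]))
    rings = np.concatenate(verts)
    m = spec.segments
    bottom_center = len(rings)
    top_center = len(rings) + 1
    all_verts = np.vstack([rings, [[0.0, 0.0, z0]], [[0.0, 0.0, z2]]])

    faces: list[tuple[int, int, int]] = []
    for lv in range(len(levels) - 1):
        a0, b0 = lv * m, (lv + 1) * m
        for i in range(m):
            j = (i + 1) % m
            # outward walls: CCW seen from outside the solid
            faces.append((a0 + i, a0 + j, b0 + j))
            faces.append((a0 + i, b0 + j, b0 + i))
    last0 = (len(levels) - 1) * m
    for i in range(m):
        j = (i + 1) % m
        faces.append((bottom_center, j, i))          # bottom cap faces −z
        faces.append((top_center, last0 + i, last0 + j))  # top cap faces +z

    mesh = TriangleMesh(all_verts, np.array(faces, dtype=np.int64))
    # orient canonical +z onto the requested axis
    z_hat = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(spec.axis @ z_hat, -1.0, 1.0))
    if c < 1.0 - 1e-15:
        if c > -1.0 + 1e-12:
            rot_axis = np.cross(z_hat, spec.axis)
            rot_axis = rot_axis / np.linalg.norm(rot_axis)
            angle = float(np.arccos(c))
        else:
            rot_axis, angle = np.array([1.0, 0.0, 0.0]), np.pi
        mesh.vertices = mesh.vertices @ _rodrigues(rot_axis, angle).T
    mesh.vertices = mesh.vertices + spec.center
    mesh.validate()
    return mesh


def hole_meshes_for(
    holes: list[PlacedHole],
    plate_thickness: float,
    spec: HoleSpec | None = None,
    overshoot: float = 0.2,
) -> list[TriangleMesh]:
    """One cutting mesh per placed hole, tall enough to pierce both faces.

    All holes share one countersink geometry; the total height is the plate
    thickness plus ``overshoot`` on each side so the Boolean always cuts
    through cleanly.
    """
    base = spec or HoleSpec()
    height = plate_thickness + 2.0 * overshoot
    meshes = []
    for h in holes:
        s = HoleSpec(
            shaft_diameter=base.shaft_diameter,
            head_diameter=base.head_diameter,
            height=height,
            head_angle_deg=base.head_angle_deg,
            center=h.center,
            axis=h.axis,
            segments=base.segments,
        )
        meshes.append(build_hole_mesh(s))
    return meshes
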