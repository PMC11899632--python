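"""Sweep a rectangular cross-section along the smoothed path.

At every path sample n a local frame is built from the forward-difference
tangent v_n = c_n − c_{n−1} and the angulation vector u_n = b_n − c_n
pointing from the path to the guide curve.  The canonical rectangle (plate
thickness t along x, plate width 2H along z, normal +y) is rotated in the
same staged way the construction is defined: a z-rotation setting the
tangent's azimuth, an axis-angle rotation about the updated in-plane axis
setting its elevation, a translation to c_n, and finally a roll by the
signed angle γ_n about v̂_n that brings the rectangle's long axis parallel
to the projection of û_n into the section plane.

Near screw holes the half-height is widened to the boss circle, and in the
end zones it follows the circle ordinate √((D/2)² − k²) exactly so the
plate terminates in a disc of diameter D around each end hole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCurveError, DegenerateGeometryError, ParameterError
from .trace_curves import TraceCurvePair

log = logging.getLogger(__name__)

_UNIT_TOL = 1e-12
_PARALLEL_TOL_RAD = 1e-6


@dataclass
class CrossSection:
    """Plate cross-section: thickness (short side) and width (long side), mm."""

    thickness: float = 2.0
    width: float = 4.62

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.width <= 0:
            raise ParameterError("cross-section dimensions must be positive")

    @property
    def half_height(self) -> float:
        return self.width / 2.0


@dataclass
class SweepFrame:
    """Local frame of one path sample."""

    center: np.ndarray
    tangent: np.ndarray
    angulation: np.ndarray
    azimuth: float
    elevation: float
    roll: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.tangent = np.asarray(self.tangent, dtype=float).reshape(3)
        self.angulation = np.asarray(self.angulation, dtype=float).reshape(3)


@dataclass
class PlacedRectangle:
    """Four transformed corners of one swept cross-section.

    Corner order: g1 = (+t/2, +H), g2 = (+t/2, −H), g3 = (−t/2, −H),
    g4 = (−t/2, +H) in local (thickness, width) coordinates, a CCW loop
    about the section normal, so ½(g1 + g4) − c points along the long axis.
    """

    corners: np.ndarray
    frame: SweepFrame
    half_height: float

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 3)

    @property
    def centroid(self) -> np.ndarray:
        return self.corners.mean(axis=0)

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.corners[1] - self.corners[0], self.corners[3] - self.corners[0])
        nn = np.linalg.norm(n)
        if nn < _UNIT_TOL:
            raise DegenerateGeometryError("rectangle has zero area")
        return n / nn


@dataclass
class HoleLayout:
    """Screw-hole centers on the path plus the screw/boss diameters."""

    centers: list = field(default_factory=list)
    screw_diameter: float = 2.0
    boss_diameter: float = 6.0

    def __post_init__(self) -> None:
        if not self.boss_diameter > self.screw_diameter > 0:
            raise ParameterError("need boss diameter D > screw diameter d > 0")
        self.centers = [np.asarray(c, dtype=float).reshape(3) for c in self.centers]


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

def compute_frames(curves: TraceCurvePair, guide_sign: float = 1.0) -> list[SweepFrame]:
    """Per-sample tangent/angulation frames.

    The tangent is the normalized backward difference c_n − c_{n−1}; the
    first sample copies the second (its own difference is undefined).  The
    angulation vector is b_n − c_n, optionally sign-flipped via
    ``guide_sign`` for plans whose guide sits on the other side of the path.
    """
    path, guide = curves.path, curves.guide
    if len(path) < 2:
        raise DegenerateCurveError("need at least 2 path samples")
    diffs = np.diff(path, axis=0)
    lens = np.linalg.norm(diffs, axis=1)
    bad = np.nonzero(lens < _UNIT_TOL)[0]
    if bad.size:
        raise DegenerateCurveError(f"zero-length tangent at path sample {bad[0] + 1}")
    tangents = np.vstack([diffs[0], diffs]) / np.concatenate([[lens[0]], lens])[:, None]
    u_raw = guide_sign * (guide - path)
    u_lens = np.linalg.norm(u_raw, axis=1)
    bad = np.nonzero(u_lens < _UNIT_TOL)[0]
    if bad.size:
        raise DegenerateCurveError(f"guide coincides with path at sample {bad[0]}")
    u_hat = u_raw / u_lens[:, None]
    frames = []
    for c, v, u in zip(path, tangents, u_hat):
        frames.append(
            SweepFrame(
                center=c,
                tangent=v,
                angulation=u,
                azimuth=float(np.arctan2(v[1], v[0])),
                elevation=float(np.arctan2(v[2], np.hypot(v[0], v[1]))),
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Rectangle placement
# ---------------------------------------------------------------------------

def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Axis-angle rotation matrix (axis must be unit length)."""
    ax, ay, az = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + ax * ax * C, ax * ay * C - az * s, ax * az * C + ay * s],
            [ay * ax * C + az * s, c + ay * ay * C, ay * az * C - ax * s],
            [az * ax * C - ay * s, az * ay * C + ax * s, c + az * az * C],
        ]
    )


def canonical_corners(thickness: float, half_height: float) -> np.ndarray:
    t2, h = thickness / 2.0, half_height
    return np.array(
        [[t2, 0.0, h], [t2, 0.0, -h], [-t2, 0.0, -h], [-t2, 0.0, h]]
    )


def place_rectangle(
    frame: SweepFrame, section: CrossSection, half_height: float | None = None
) -> PlacedRectangle:
    """Transform the canonical rectangle into the frame's section plane.

    Staging: Rz(azimuth − 90°) points the canonical +y normal at the
    tangent's azimuth; an axis-angle rotation about the updated short-side
    axis lifts it to the tangent's elevation; the corners are translated to
    the sample; and a final roll γ about v̂ aligns the long axis with the
    in-plane projection of the angulation vector.
    """
    if half_height is None:
        half_height = section.half_height
    if half_height <= 0:
        raise ParameterError("half_height must be positive")
    v = frame.tangent / np.linalg.norm(frame.tangent)
    u = frame.angulation / np.linalg.norm(frame.angulation)
    u_proj = u - (u @ v) * v
    if np.linalg.norm(u_proj) < _PARALLEL_TOL_RAD:
        raise DegenerateCurveError(
            "guide direction parallel to path tangent: roll is undefined"
        )

    g = canonical_corners(section.thickness, half_height)
    rz = _rodrigues(np.array([0.0, 0.0, 1.0]), frame.azimuth - np.pi / 2.0)
    a_y = rz @ np.array([1.0, 0.0, 0.0])  # updated in-plane (short-side) axis
    ry = _rodrigues(a_y, frame.elevation)
    corners = (ry @ rz @ g.T).T

    w = 0.5 * (corners[0] + corners[3])  # long-axis direction before roll
    gamma = float(np.arctan2(np.cross(w, u) @ v, w @ u))
    corners = (_rodrigues(v, gamma) @ corners.T).T + frame.center
    placed_frame = SweepFrame(
        center=frame.center,
        tangent=v,
        angulation=u,
        azimuth=frame.azimuth,
        elevation=frame.elevation,
        roll=gamma,
    )
    return PlacedRectangle(corners=corners, frame=placed_frame, half_height=half_height)


# ---------------------------------------------------------------------------
# Hole-adaptive half-height
# ---------------------------------------------------------------------------

def boss_half_height(k: float, boss_diameter: float) -> float:
    """Circle ordinate (D/2)·sin(arccos(k/(D/2))) = √((D/2)² − k²); 0 beyond."""
    r = boss_diameter / 2.0
    if k >= r:
        return 0.0
    return r * np.sin(np.arccos(k / r))


def local_half_height(
    c_n: np.ndarray,
    layout: HoleLayout,
    base_half_height: float,
    is_end_zone: bool = False,
) -> float:
    """Half-height at a sample: base height widened to the boss circle near a
    hole; in an end zone the circle ordinate itself (disc termination)."""
    if not layout.centers:
        return base_half_height
    c_n = np.asarray(c_n, dtype=float).reshape(3)
    k = min(float(np.linalg.norm(c_n - h)) for h in layout.centers)
    r = layout.boss_diameter / 2.0
    if is_end_zone:
        return boss_half_height(k, layout.boss_diameter)
    if k > r:
        return base_half_height
    return max(base_half_height, boss_half_height(k, layout.boss_diameter))


# ---------------------------------------------------------------------------
# Full sweep
# ---------------------------------------------------------------------------

#: Sections thinner than this (mm) at the very plate tips are dropped so the
#: end discs do not terminate in zero-area rectangles.
MIN_TIP_HALF_HEIGHT_MM = 0.05


def sweep(
    curves: TraceCurvePair,
    section: CrossSection,
    layout: HoleLayout,
    guide_sign: float = 1.0,
) -> list[PlacedRectangle]:
    """One placed rectangle per path sample, ordered along the path.

    When the layout has holes, its first and last centers are taken as the
    end holes; samples outside them (toward the termini) form the end zones
    where the height follows the disc circle.  Near-degenerate tip sections
    are trimmed.
    """
    frames = compute_frames(curves, guide_sign=guide_sign)
    path = curves.path
    if not layout.centers:
        return [place_rectangle(f, section) for f in frames]

    first, last = layout.centers[0], layout.centers[-1]
    i_first = int(np.argmin(np.linalg.norm(path - first, axis=1)))
    i_last = int(np.argmin(np.linalg.norm(path - last, axis=1)))
    rects: list[PlacedRectangle] = []
    for i, frame in enumerate(frames):
        end_zone = i < i_first or i > i_last
        hh = local_half_height(frame.center, layout, section.half_height, is_end_zone=end_zone)
        if hh < MIN_TIP_HALF_HEIGHT_MM:
            if end_zone:
                continue  # trim the degenerate tip sliver
            raise DegenerateGeometryError(f"vanishing section height at sample {i}")
        rects.append(place_rectangle(frame, section, half_height=hh))
    if len(rects) < 2:
        raise DegenerateGeometryError("sweep produced fewer than 2 usable sections")
    log.info("swept %d sections (%d trimmed at tips)", len(rects), len(frames) - len(rects))
    return rects
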