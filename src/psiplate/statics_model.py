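"""Rigid-body static equilibrium of the mandible under muscle loading.

During clenching, the masticatory muscles load the mandible while it is
resisted at one tooth contact and at the two temporomandibular joints
(condyles).  Force and moment balance give six equations for the nine
unknown reaction components (tooth T, left condyle CL, right condyle CR);
the system is closed with three angle assumptions on the reaction
directions: the tooth resultant's lateral angle α (tan α = Tz/Ty) and
frontal angle β (tan β = Tz/Tx), and the left condyle's frontal angle γ
(tan γ = CLz/CLx).  The angle rows are written in the singular-safe form
sin θ·(denominator) − cos θ·(numerator) = 0 so the customary γ = 90°
(reaction in the y–z plane) poses no difficulty.

The solved tooth reaction magnitude |T| then scales literature muscle
forces to a patient's measured bite force: s = bite / |T|, applied to every
force vector with attachments unchanged.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SingularSystemError

#: Default reaction-direction angles, degrees: lateral tooth angle α,
#: frontal tooth angle β, left-condyle frontal angle γ.
DEFAULT_ALPHA_DEG = 100.0
DEFAULT_BETA_DEG = 70.0
DEFAULT_GAMMA_DEG = 90.0
#: Measured right-molar bite force used for scaling, N.
DEFAULT_BITE_FORCE_N = 91.0

_MUSCLE_COLUMNS = ["name", "side", "Fx_N", "Fy_N", "Fz_N", "ax_mm", "ay_mm", "az_mm"]


@dataclass
class MuscleAction:
    """One muscle's force vector (N) and its attachment point (mm)."""

    name: str
    force: np.ndarray
    attachment: np.ndarray
    side: str = ""

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float).reshape(3)
        self.attachment = np.asarray(self.attachment, dtype=float).reshape(3)
        if not (np.isfinite(self.force).all() and np.isfinite(self.attachment).all()):
            raise ParameterError(f"muscle {self.name}: non-finite force or attachment")


@dataclass
class ReactionGeometry:
    """Reaction points (mm) and direction angles (degrees)."""

    tooth: np.ndarray
    condyle_left: np.ndarray
    condyle_right: np.ndarray
    alpha_deg: float = DEFAULT_ALPHA_DEG
    beta_deg: float = DEFAULT_BETA_DEG
    gamma_deg: float = DEFAULT_GAMMA_DEG

    def __post_init__(self) -> None:
        self.tooth = np.asarray(self.tooth, dtype=float).reshape(3)
        self.condyle_left = np.asarray(self.condyle_left, dtype=float).reshape(3)
        self.condyle_right = np.asarray(self.condyle_right, dtype=float).reshape(3)
        cross = np.cross(self.condyle_left - self.tooth, self.condyle_right - self.tooth)
        if np.linalg.norm(cross) < 1e-9:
            raise ParameterError("tooth and condyle points are collinear")


@dataclass
class StaticsSolution:
    """Reactions (N), their magnitudes, residuals and the joint/tooth ratio."""

    T: np.ndarray
    CL: np.ndarray
    CR: np.ndarray
    force_residual: float = 0.0
    moment_residual: float = 0.0
    scale: float | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        self.CL = np.asarray(self.CL, dtype=float).reshape(3)
        self.CR = np.asarray(self.CR, dtype=float).reshape(3)

    @property
    def T_mag(self) -> float:
        return float(np.linalg.norm(self.T))

    @property
    def CL_mag(self) -> float:
        return float(np.linalg.norm(self.CL))

    @property
    def CR_mag(self) -> float:
        return float(np.linalg.norm(self.CR))


def solve_reactions(
    muscles: list[MuscleAction], geom: ReactionGeometry
) -> StaticsSolution:
    """Solve the 9×9 linear system for the three reaction vectors.

    Rows: ΣF = 0 (3), ΣM = 0 about the origin (3), and the three
    singular-safe angle constraints.  Moments may be taken about any point
    for a balanced system; the origin is used.
    """
    if not muscles:
        raise ParameterError("need at least one muscle action")
    f_net = np.sum([m.force for m in muscles], axis=0)
    m_net = np.sum([np.cross(m.attachment, m.force) for m in muscles], axis=0)

    def skew(r: np.ndarray) -> np.ndarray:
        return np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])

    A = np.zeros((9, 9))
    rhs = np.zeros(9)
    # unknown ordering: T (0:3), CL (3:6), CR (6:9)
    A[0:3, 0:3] = A[0:3, 3:6] = A[0:3, 6:9] = np.eye(3)
    rhs[0:3] = -f_net
    A[3:6, 0:3] = skew(geom.tooth)
    A[3:6, 3:6] = skew(geom.condyle_left)
    A[3:6, 6:9] = skew(geom.condyle_right)
    rhs[3:6] = -m_net
    al, be, ga = np.radians([geom.alpha_deg, geom.beta_deg, geom.gamma_deg])
    # tan α = Tz/Ty  →  sin α · Ty − cos α · Tz = 0
    A[6, 1], A[6, 2] = np.sin(al), -np.cos(al)
    # tan β = Tz/Tx  →  sin β · Tx − cos β · Tz = 0
    A[7, 0], A[7, 2] = np.sin(be), -np.cos(be)
    # tan γ = CLz/CLx  →  sin γ · CLx − cos γ · CLz = 0
    A[8, 3], A[8, 5] = np.sin(ga), -np.cos(ga)

    u, s, vt = np.linalg.svd(A)
    if s[-1] < 1e-10 * s[0]:
        raise SingularSystemError(
            f"reaction system is rank deficient; null direction {np.round(vt[-1], 4)}"
        )
    x = np.linalg.solve(A, rhs)
    T, CL, CR = x[0:3], x[3:6], x[6:9]
    f_res = float(np.linalg.norm(T + CL + CR + f_net))
    m_res = float(
        np.linalg.norm(
            np.cross(geom.tooth, T)
            + np.cross(geom.condyle_left, CL)
            + np.cross(geom.condyle_right, CR)
            + m_net
        )
    )
    return StaticsSolution(T=T, CL=CL, CR=CR, force_residual=f_res, moment_residual=m_res)


def joint_tooth_ratio(sol: StaticsSolution) -> float:
    """(|CL| + |CR|) / |T| — total condylar over tooth reaction force."""
    t = sol.T_mag
    if t == 0.0:
        if sol.CL_mag == 0.0 and sol.CR_mag == 0.0:
            return 0.0
        raise ParameterError("tooth reaction magnitude is zero; ratio undefined")
    return (sol.CL_mag + sol.CR_mag) / t


def scale_muscle_forces(
    muscles: list[MuscleAction],
    tooth_reaction_magnitude: float,
    measured_bite: float = DEFAULT_BITE_FORCE_N,
) -> tuple[list[MuscleAction], float]:
    """Scale every force by s = measured bite / solved tooth reaction.

    Attachments are unchanged; returns the scaled actions and s.
    """
    if tooth_reaction_magnitude <= 0 or measured_bite <= 0:
        raise ParameterError("tooth reaction and bite force must be positive")
    s = measured_bite / tooth_reaction_magnitude
    scaled = [
        MuscleAction(m.name, s * m.force, m.attachment.copy(), m.side) for m in muscles
    ]
    return scaled, s


# ---------------------------------------------------------------------------
# Muscle-table I/O
# ---------------------------------------------------------------------------

def muscles_from_frame(df: pd.DataFrame) -> list[MuscleAction]:
    missing = [c for c in _MUSCLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"muscle table missing columns {missing}")
    return [
        MuscleAction(
            name=row["name"],
            side=row["side"],
            force=[row["Fx_N"], row["Fy_N"], row["Fz_N"]],
            attachment=[row["ax_mm"], row["ay_mm"], row["az_mm"]],
        )
        for _, row in df.iterrows()
    ]


def muscles_to_frame(muscles: list[MuscleAction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": m.name,
                "side": m.side,
                "Fx_N": m.force[0],
                "Fy_N": m.force[1],
                "Fz_N": m.force[2],
                "ax_mm": m.attachment[0],
                "ay_mm": m.attachment[1],
                "az_mm": m.attachment[2],
            }
            for m in muscles
        ]
    )


def load_muscle_csv(path: str | Path) -> list[MuscleAction]:
    return muscles_from_frame(pd.read_csv(path, comment="#"))


def load_reference_muscles() -> list[MuscleAction]:
    """Literature clenching muscle forces for twelve masticatory muscles.

    Force vectors are the published right-molar-clenching values; the
    attachment coordinates are synthetic (plausible mandible geometry, not
    measured) — see the packaged CSV header.
    """
    ref = importlib.resources.files("psiplate.data").joinpath(
        "muscle_forces_literature_synthetic_attachments.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return load_muscle_csv(path)


def load_reference_scaled_table() -> pd.DataFrame:
    """Published bite-force-scaled muscle table (N), for cross-checks."""
    ref = importlib.resources.files("psiplate.data").joinpath(
        "muscle_forces_scaled_printed.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")
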