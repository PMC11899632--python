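"""Turn sparse surgeon-picked point sets into smooth, paired sweep curves.

Two point arrays define the plate: C1 (the sweep path along the bone) and
C2 (a guide curve across the surface that controls how the cross-section
rolls).  Both are densified by natural cubic-spline interpolation against
the integer index scale ns = 1..n, smoothed by a cubic smoothing spline
with parameter P, resampled uniformly by arc length, and finally paired
index-by-index so the i-th guide point is the partner of the i-th path
point.

The smoothing objective is

    P * sum_i |y_i - S(ns_i)|^2  +  (1 - P) * int S''(ns)^2 dns

so P = 1 interpolates the data and P = 0 degenerates to the least-squares
straight line of each coordinate against ns.  For 0 < P < 1 this is the
classical penalized smoothing spline with lam = (1 - P) / P, which is the
problem :func:`scipy.interpolate.make_smoothing_spline` solves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import InvalidPlanError, ParameterError

#: Default number of interpolated points inserted between consecutive picks.
DEFAULT_Q = 10
#: Default smoothing parameter (close to interpolation; removes corner spikes).
DEFAULT_P = 0.99
#: Default uniform spacing of sweep sections along the smoothed path, mm.
DEFAULT_PITCH_MM = 0.5

_MIN_STEP_MM = 1e-9


@dataclass
class PlanPoints:
    """Raw picked points: path picks C1, guide picks C2, hole picks P1 (mm)."""

    C1: np.ndarray
    C2: np.ndarray
    P1: np.ndarray
    q: int = DEFAULT_Q
    P: float = DEFAULT_P

    def __post_init__(self) -> None:
        self.C1 = np.asarray(self.C1, dtype=float).reshape(-1, 3)
        self.C2 = np.asarray(self.C2, dtype=float).reshape(-1, 3)
        self.P1 = np.asarray(self.P1, dtype=float).reshape(-1, 3)

    def validate(self) -> None:
        for name, arr, minimum in (("C1", self.C1, 2), ("C2", self.C2, 2), ("P1", self.P1, 0)):
            if len(arr) < minimum:
                raise InvalidPlanError(f"{name} needs at least {minimum} points, got {len(arr)}")
            if arr.size and not np.isfinite(arr).all():
                raise InvalidPlanError(f"{name} contains non-finite coordinates")
        for name, arr in (("C1", self.C1), ("C2", self.C2)):
            step = np.linalg.norm(np.diff(arr, axis=0), axis=1)
            if step.size and step.min() <= _MIN_STEP_MM:
                raise InvalidPlanError(f"{name} has coincident consecutive points")


@dataclass
class TraceCurvePair:
    """Densified, smoothed and index-paired sweep path and guide curve."""

    path: np.ndarray
    guide: np.ndarray
    samples_per_segment: int
    smoothing: float

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float).reshape(-1, 3)
        self.guide = np.asarray(self.guide, dtype=float).reshape(-1, 3)
        if len(self.path) != len(self.guide):
            raise InvalidPlanError("path and guide must have equal point counts")


# ---------------------------------------------------------------------------
# Plan file I/O (JSON of [x, y, z] mm triples)
# ---------------------------------------------------------------------------

def load_plan(path: str | Path) -> PlanPoints:
    data = json.loads(Path(path).read_text())
    try:
        plan = PlanPoints(
            C1=np.array(data["C1"], dtype=float),
            C2=np.array(data["C2"], dtype=float),
            P1=np.array(data.get("P1", np.zeros((0, 3))), dtype=float).reshape(-1, 3),
            q=int(data.get("q", DEFAULT_Q)),
            P=float(data.get("P", DEFAULT_P)),
        )
    except (KeyError, ValueError) as exc:
        raise InvalidPlanError(f"{path}: malformed plan file: {exc}") from exc
    plan.validate()
    return plan


def save_plan(plan: PlanPoints, path: str | Path) -> None:
    payload = {
        "C1": plan.C1.tolist(),
        "C2": plan.C2.tolist(),
        "P1": plan.P1.tolist(),
        "q": plan.q,
        "P": plan.P,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def interpolate(points: np.ndarray, q: int) -> np.ndarray:
    """Insert ``q`` natural-cubic-spline points between each pair of picks.

    The spline for each coordinate is parameterized on ns = 1..n; output has
    n + (n-1)*q points evaluated at uniformly spaced parameter values, and
    reproduces the input exactly at integer parameters.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    if n < 2:
        raise InvalidPlanError(f"interpolation needs >= 2 points, got {n}")
    if q < 0:
        raise ParameterError("q must be >= 0")
    if q == 0:
        return points.copy()
    ns = np.arange(1, n + 1, dtype=float)
    ts = np.linspace(1.0, float(n), n + (n - 1) * q)
    spline = CubicSpline(ns, points, axis=0, bc_type="natural")
    out = spline(ts)
    # pin originals exactly at integer parameters (indices 0, q+1, 2(q+1), ...)
    out[:: q + 1] = points
    return out


def smooth(points: np.ndarray, P: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Cubic smoothing spline of each coordinate column against ns = 1..n.

    Returns S(ns_i) for the spline minimizing
    ``P * sum w_i |y_i - S|^2 + (1-P) * int S''^2``; P=1 reproduces the data,
    P=0 yields the weighted least-squares straight line.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    if n < 3:
        raise InvalidPlanError(f"smoothing needs >= 3 points, got {n}")
    if not (0.0 <= P <= 1.0):
        raise ParameterError(f"smoothing parameter P must be in [0, 1], got {P}")
    ns = np.arange(1, n + 1, dtype=float)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or (w <= 0).any():
        raise ParameterError("weights must be n positive reals")
    if P == 1.0:
        return points.copy()
    if P == 0.0:
        # curvature term dominates: S'' = 0, i.e. the LS line per coordinate
        design = np.stack([np.ones(n), ns], axis=1) * np.sqrt(w)[:, None]
        rhs = points * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(design, rhs, rcond=None)
        return np.stack([np.ones(n), ns], axis=1) @ coef
    lam = (1.0 - P) / P
    out = np.empty_like(points)
    for col in range(3):
        if n >= 5:
            out[:, col] = make_smoothing_spline(ns, points[:, col], w=w, lam=lam)(ns)
        else:
            out[:, col] = _penalized_values_small_n(points[:, col], w, lam)
    return out


def _penalized_values_small_n(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Knot values of the penalized natural spline for n = 3 or 4.

    Uses the Green–Silverman roughness matrix K = Q R^-1 Q^T on the uniform
    knot grid (h = 1), solving (W + lam K) g = W y directly.
    """
    n = len(y)
    h = 1.0
    m = n - 2
    Q = np.zeros((n, m))
    for j in range(m):
        Q[j, j] = 1.0 / h
        Q[j + 1, j] = -2.0 / h
        Q[j + 2, j] = 1.0 / h
    R = np.zeros((m, m))
    for j in range(m):
        R[j, j] = 2.0 * h / 3.0
        if j + 1 < m:
            R[j, j + 1] = R[j + 1, j] = h / 6.0
    K = Q @ np.linalg.solve(R, Q.T)
    W = np.diag(w)
    return np.linalg.solve(W + lam * K, W @ y)


def resample_by_arclength(points: np.ndarray, pitch: float | None = None,
                          n_samples: int | None = None) -> np.ndarray:
    """Resample a polyline at uniform chord-length spacing.

    Exactly one of ``pitch`` (target spacing, mm) or ``n_samples`` is given;
    endpoints are always retained.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 2:
        raise InvalidPlanError("resampling needs >= 2 points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= _MIN_STEP_MM:
        raise InvalidPlanError("curve has zero length")
    if n_samples is None:
        if pitch is None or pitch <= 0:
            raise ParameterError("pitch must be positive")
        n_samples = max(2, int(round(total / pitch)) + 1)
    targets = np.linspace(0.0, total, n_samples)
    return np.stack([np.interp(targets, s, points[:, k]) for k in range(3)], axis=1)


def pair_guide(path: np.ndarray, guide_raw: np.ndarray) -> np.ndarray:
    """Resample the guide to match the path and orient it to minimize
    the summed index-wise Euclidean distance.

    Ordering along the guide is preserved: only an arc-length resampling and
    possibly a whole-curve reversal are applied, never per-point permutations.
    """
    path = np.asarray(path, dtype=float).reshape(-1, 3)
    guide_raw = np.asarray(guide_raw, dtype=float).reshape(-1, 3)
    if len(guide_raw) < 2:
        raise InvalidPlanError("guide curve needs >= 2 points")
    forward = resample_by_arclength(guide_raw, n_samples=len(path))
    reverse = forward[::-1]
    d_fwd = np.linalg.norm(path - forward, axis=1).sum()
    d_rev = np.linalg.norm(path - reverse, axis=1).sum()
    return forward if d_fwd <= d_rev else reverse.copy()


def build_trace_curves(
    plan: PlanPoints,
    q: int | None = None,
    P: float | None = None,
    pitch_mm: float = DEFAULT_PITCH_MM,
) -> TraceCurvePair:
    """Full curve stage: interpolate, smooth, resample the path by arc
    length, and pair the guide to it."""
    plan.validate()
    q = plan.q if q is None else q
    P = plan.P if P is None else P
    path = resample_by_arclength(smooth(interpolate(plan.C1, q), P), pitch=pitch_mm)
    guide_dense = smooth(interpolate(plan.C2, q), P)
    guide = pair_guide(path, guide_dense)
    pair = TraceCurvePair(path=path, guide=guide, samples_per_segment=q, smoothing=P)
    step = np.linalg.norm(np.diff(pair.path, axis=0), axis=1)
    if step.min() <= _MIN_STEP_MM:
        raise InvalidPlanError("smoothed path has coincident consecutive samples")
    return pair
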