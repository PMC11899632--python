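"""Spline interpolation, smoothing-spline behaviour and guide pairing."""

import numpy as np
import pytest
from scipy.sparse import diags, eye, vstack as sp_vstack
from scipy.sparse.linalg import spsolve

from psiplate import interpolate, pair_guide, resample_by_arclength, smooth
from psiplate.errors import InvalidPlanError, ParameterError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def natural_spline_oracle(y: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Natural cubic spline through (i+1, y_i) via the tridiagonal M-system."""
    n = len(y)
    rhs = 6.0 * (y[2:] - 2 * y[1:-1] + y[:-2])
    m_inner = np.linalg.solve(
        np.diag(4.0 * np.ones(n - 2)) + np.diag(np.ones(n - 3), 1) + np.diag(np.ones(n - 3), -1),
        rhs,
    )
    M = np.concatenate([[0.0], m_inner, [0.0]])
    out = np.empty_like(ts)
    for k, t in enumerate(ts):
        i = min(int(np.floor(t - 1)), n - 2)
        u = t - 1 - i
        out[k] = (
            M[i] * (1 - u) ** 3 / 6
            + M[i + 1] * u**3 / 6
            + (y[i] - M[i] / 6) * (1 - u)
            + (y[i + 1] - M[i + 1] / 6) * u
        )
    return out


def discretized_smoothing_oracle(y: np.ndarray, P: float, m: int) -> np.ndarray:
    """Finite-difference minimizer of the smoothing objective on a dense grid."""
    n = len(y)
    grid = (n - 1) * m + 1
    h = 1.0 / m
    data_idx = np.arange(0, grid, m)
    S = eye(grid, format="csr")[data_idx]
    D2 = diags(
        [np.ones(grid - 2), -2 * np.ones(grid - 2), np.ones(grid - 2)],
        [0, 1, 2],
        shape=(grid - 2, grid),
    ) / h**2
    A = sp_vstack([np.sqrt(P) * S, np.sqrt((1 - P) * h) * D2]).tocsr()
    b = np.concatenate([np.sqrt(P) * y, np.zeros(grid - 2)])
    g = spsolve((A.T @ A).tocsc(), A.T @ b)
    return g[data_idx]


def objective(y: np.ndarray, s: np.ndarray, P: float) -> float:
    """Discrete version of the smoothing objective at the knots."""
    resid = float(np.sum((y - s) ** 2))
    curv = float(np.sum(np.diff(s, 2) ** 2))
    return P * resid + (1 - P) * curv


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def test_interpolation_of_collinear_points_stays_on_line():
    pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    out = interpolate(pts, q=1)
    np.testing.assert_allclose(out[1], [0.5, 0, 0], atol=1e-12)
    np.testing.assert_allclose(out[3], [1.5, 0, 0], atol=1e-12)
    np.testing.assert_allclose(out[:, 1:], 0, atol=1e-12)


def test_interpolation_q0_is_identity():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(6, 3))
    np.testing.assert_array_equal(interpolate(pts, q=0), pts)


def test_interpolation_matches_tridiagonal_oracle():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(5, 3)) * 10
    q = 3
    out = interpolate(pts, q=q)
    ts = np.linspace(1, 5, 5 + 4 * q)
    for col in range(3):
        expected = natural_spline_oracle(pts[:, col], ts)
        np.testing.assert_allclose(out[:, col], expected, atol=1e-9)


def test_interpolation_rejects_single_point():
    with pytest.raises(InvalidPlanError):
        interpolate(np.array([[0.0, 0.0, 0.0]]), q=2)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_smoothing_p1_reproduces_data():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(9, 3))
    np.testing.assert_allclose(smooth(pts, P=1.0), pts, atol=1e-9)


def test_smoothing_p0_is_least_squares_line():
    pts = np.array([[1, 0, 0], [2, 1, 0], [3, 2, 0]], dtype=float)
    out = smooth(pts, P=0.0)
    np.testing.assert_allclose(out, pts, atol=1e-9)  # data already on a line
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(8, 3))
    out = smooth(pts, P=0.0)
    ns = np.arange(1, 9)
    for col in range(3):
        coef = np.polyfit(ns, pts[:, col], 1)
        np.testing.assert_allclose(out[:, col], np.polyval(coef, ns), atol=1e-9)


def test_smoothing_p0_is_idempotent():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(7, 3))
    once = smooth(pts, P=0.0)
    np.testing.assert_allclose(smooth(once, P=0.0), once, atol=1e-9)


def test_mid_p_matches_dense_variational_minimizer():
    rng = np.random.default_rng(5)
    ns = np.arange(1.0, 8.0)
    y = (ns - 4) ** 2 + 0.3 * rng.standard_normal(7)
    pts = np.stack([y, np.zeros(7), np.zeros(7)], axis=1)
    P = 0.5
    ours = smooth(pts, P=P)[:, 0]
    # Richardson-extrapolated finite-difference minimization; grids stay
    # coarse enough that the h^-4 normal-equation conditioning is harmless
    g1 = discretized_smoothing_oracle(y, P, m=64)
    g2 = discretized_smoothing_oracle(y, P, m=128)
    dense = (4 * g2 - g1) / 3
    np.testing.assert_allclose(ours, dense, atol=1e-6)
    # returned spline beats both extreme fits on the objective
    interp = y
    line = np.polyval(np.polyfit(ns, y, 1), ns)
    assert objective(y, ours, P) <= objective(y, interp, P) + 1e-12
    assert objective(y, ours, P) <= objective(y, line, P) + 1e-12


@pytest.mark.parametrize("n", [3, 4])
def test_small_n_smoothing_matches_dense_minimizer(n):
    rng = np.random.default_rng(6)
    y = rng.normal(size=n)
    pts = np.stack([y, np.zeros(n), np.zeros(n)], axis=1)
    ours = smooth(pts, P=0.7)[:, 0]
    g1 = discretized_smoothing_oracle(y, 0.7, m=64)
    g2 = discretized_smoothing_oracle(y, 0.7, m=128)
    np.testing.assert_allclose(ours, (4 * g2 - g1) / 3, atol=1e-6)


def test_smoothing_curvature_monotone_in_p():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(10, 3))
    curvatures = []
    for P in [0.0, 0.25, 0.5, 0.75, 1.0]:
        s = smooth(pts, P=P)
        curvatures.append(float(np.sum(np.diff(s, 2, axis=0) ** 2)))
    assert all(a <= b + 1e-9 for a, b in zip(curvatures, curvatures[1:]))


def test_smoothing_rejects_bad_parameter():
    pts = np.zeros((5, 3))
    with pytest.raises(ParameterError):
        smooth(pts, P=1.5)


# ---------------------------------------------------------------------------
# pairing and resampling
# ---------------------------------------------------------------------------

def test_pair_guide_flips_reversed_guide():
    path = np.stack([np.linspace(0, 10, 21), np.zeros(21), np.zeros(21)], axis=1)
    guide = np.stack([np.linspace(10, 0, 15), np.ones(15), np.zeros(15)], axis=1)
    paired = pair_guide(path, guide)
    assert len(paired) == len(path)
    d = np.linalg.norm(path - paired, axis=1)
    np.testing.assert_allclose(d, 1.0, atol=1e-9)  # parallel at distance 1


def test_pair_guide_identical_curves_zero_distance():
    rng = np.random.default_rng(8)
    steps = rng.normal(size=(11, 3))
    steps = 0.5 * steps / np.linalg.norm(steps, axis=1, keepdims=True)  # uniform chords
    path = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    paired = pair_guide(path, path)
    assert np.linalg.norm(path - paired, axis=1).sum() < 1e-9


def test_pair_guide_picks_better_orientation_on_arcs():
    theta = np.linspace(0, np.pi / 2, 50)
    path = np.stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros(50)], axis=1)
    guide = np.stack([12 * np.cos(theta), 12 * np.sin(theta), np.zeros(50)], axis=1)
    chosen = pair_guide(path, guide[::-1])  # given reversed
    alt = chosen[::-1]
    d_chosen = np.linalg.norm(path - chosen, axis=1).sum()
    d_alt = np.linalg.norm(path - alt, axis=1).sum()
    assert d_chosen <= d_alt


def test_resample_by_arclength_uniform_spacing():
    rng = np.random.default_rng(9)
    pts = np.cumsum(rng.uniform(0.2, 1.0, size=(30, 3)), axis=0)
    out = resample_by_arclength(pts, pitch=0.5)
    steps = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert steps.std() / steps.mean() < 0.2
    np.testing.assert_allclose(out[0], pts[0], atol=1e-12)
    np.testing.assert_allclose(out[-1], pts[-1], atol=1e-12)
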