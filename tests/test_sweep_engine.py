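"""Frame construction, rectangle placement and hole-adaptive heights."""

import numpy as np
import pytest

from psiplate import (
    CrossSection,
    HoleLayout,
    SweepFrame,
    TraceCurvePair,
    boss_half_height,
    compute_frames,
    local_half_height,
    place_rectangle,
    sweep,
)
from psiplate.errors import DegenerateCurveError


def _curves(path, guide):
    return TraceCurvePair(path=path, guide=guide, samples_per_segment=0, smoothing=1.0)


def _frame(v, u, c=(0.0, 0.0, 0.0)):
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    return SweepFrame(
        center=np.asarray(c, dtype=float),
        tangent=v,
        angulation=np.asarray(u, dtype=float),
        azimuth=float(np.arctan2(v[1], v[0])),
        elevation=float(np.arctan2(v[2], np.hypot(v[0], v[1]))),
    )


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def test_straight_path_frames():
    n = 10
    path = np.stack([np.zeros(n), np.linspace(0, 9, n), np.zeros(n)], axis=1)
    guide = path + [0.0, 0.0, 3.0]
    frames = compute_frames(_curves(path, guide))
    for f in frames:
        np.testing.assert_allclose(f.tangent, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.angulation, [0, 0, 1], atol=1e-12)


def test_circle_tangent_perpendicular_to_radius():
    theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    path = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    guide = 1.5 * path
    frames = compute_frames(_curves(path, guide))
    dtheta = theta[1] - theta[0]
    for f, p in zip(frames[1:], path[1:]):
        cosang = abs(f.tangent @ (p / np.linalg.norm(p)))
        assert cosang < dtheta  # tangent ⟂ radius up to discretization


def test_helix_tangent_matches_analytic():
    r, pitch, n = 10.0, 2.0, 200
    t = np.linspace(0, 4 * np.pi, n)
    path = np.stack([r * np.cos(t), r * np.sin(t), pitch * t], axis=1)
    guide = path + np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
    frames = compute_frames(_curves(path, guide))
    analytic = np.stack([-r * np.sin(t), r * np.cos(t), np.full_like(t, pitch)], axis=1)
    analytic /= np.linalg.norm(analytic, axis=1, keepdims=True)
    spacing = np.linalg.norm(np.diff(path, axis=0), axis=1).max()
    bound = 2 * spacing / r
    for i in range(1, n):
        # backward difference lags the midpoint tangent by ~half a step
        mid = 0.5 * (analytic[i] + analytic[i - 1])
        mid /= np.linalg.norm(mid)
        ang = np.arccos(np.clip(frames[i].tangent @ mid, -1, 1))
        assert ang < bound


def test_degenerate_tangent_raises_with_index():
    path = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    guide = path + [0, 1, 0]
    with pytest.raises(DegenerateCurveError, match="sample 2"):
        compute_frames(_curves(path, guide))


# ---------------------------------------------------------------------------
# rectangle placement
# ---------------------------------------------------------------------------

def test_placement_canonical_orientation():
    rect = place_rectangle(_frame([0, 1, 0], [0, 0, 1]), CrossSection(2.0, 4.62))
    expected = {(1.0, 0.0, 2.31), (1.0, 0.0, -2.31), (-1.0, 0.0, -2.31), (-1.0, 0.0, 2.31)}
    got = {tuple(np.round(c, 9)) for c in rect.corners}
    assert got == expected


def test_placement_quarter_roll():
    rect = place_rectangle(_frame([0, 1, 0], [1, 0, 0]), CrossSection(2.0, 4.62))
    expected = {(2.31, 0.0, 1.0), (2.31, 0.0, -1.0), (-2.31, 0.0, -1.0), (-2.31, 0.0, 1.0)}
    got = {tuple(np.round(c, 9)) for c in rect.corners}
    assert got == expected


def test_placement_properties_random_frames():
    rng = np.random.default_rng(11)
    section = CrossSection(2.0, 4.62)
    for _ in range(1000):
        v = rng.normal(size=3)
        u = rng.normal(size=3)
        c = rng.uniform(-50, 50, 3)
        v /= np.linalg.norm(v)
        if np.linalg.norm(u - (u @ v) * v) < 1e-3:
            continue
        rect = place_rectangle(_frame(v, u, c), section)
        g = rect.corners
        # coplanarity
        n = np.cross(g[1] - g[0], g[3] - g[0])
        n /= np.linalg.norm(n)
        assert abs((g[2] - g[0]) @ n) < 1e-9
        # normal parallel tangent
        assert abs(abs(n @ v) - 1) < 1e-9
        # centroid on path
        assert np.linalg.norm(rect.centroid - c) < 1e-9
        # long side perpendicular to tangent and aligned with u projection
        long_dir = g[0] - g[1]
        long_dir /= np.linalg.norm(long_dir)
        short_dir = g[1] - g[2]
        short_dir /= np.linalg.norm(short_dir)
        assert abs(long_dir @ v) < 1e-9
        u_hat = u / np.linalg.norm(u)
        assert abs(long_dir @ u_hat) >= abs(short_dir @ u_hat) - 1e-12
        u_proj = u_hat - (u_hat @ v) * v
        u_proj /= np.linalg.norm(u_proj)
        assert long_dir @ u_proj > 1 - 1e-9  # roll maximizes projection onto û


def test_parallel_guide_raises():
    with pytest.raises(DegenerateCurveError):
        place_rectangle(_frame([0, 1, 0], [0, 1, 0]), CrossSection())


# ---------------------------------------------------------------------------
# hole-adaptive height
# ---------------------------------------------------------------------------

def test_boss_height_closed_forms():
    assert boss_half_height(0.0, 6.0) == pytest.approx(3.0)
    assert boss_half_height(3.0, 6.0) == pytest.approx(0.0)
    assert boss_half_height(1.5, 6.0) == pytest.approx(3.0 * np.sqrt(3) / 2, abs=1e-12)


def test_local_half_height_interior_widens_never_narrows():
    layout = HoleLayout(centers=[np.array([0.0, 0.0, 0.0])], boss_diameter=6.0)
    H = 2.31
    assert local_half_height([10, 0, 0], layout, H) == H
    assert local_half_height([0, 0, 0], layout, H) == pytest.approx(3.0)
    # at k = 2.9 the boss ordinate is below H: stays at H
    k = 2.9
    assert boss_half_height(k, 6.0) < H
    assert local_half_height([k, 0, 0], layout, H) == H


def test_sweep_straight_no_holes_gives_congruent_sections():
    n = 20
    path = np.stack([np.linspace(0, 19, n), np.zeros(n), np.zeros(n)], axis=1)
    guide = path + [0, 0, 2]
    rects = sweep(_curves(path, guide), CrossSection(2.0, 4.62), HoleLayout())
    assert len(rects) == n
    first = rects[0].corners - rects[0].centroid
    for r in rects[1:]:
        np.testing.assert_allclose(r.corners - r.centroid, first, atol=1e-9)


def test_sweep_with_interior_hole_raises_height_profile():
    n = 81
    path = np.stack([np.linspace(0, 40, n), np.zeros(n), np.zeros(n)], axis=1)
    guide = path + [0, 0, 2]
    center = np.array([20.0, 0.0, 0.0])
    layout = HoleLayout(
        centers=[np.array([3.0, 0, 0]), center, np.array([37.0, 0, 0])],
        boss_diameter=6.0,
    )
    rects = sweep(_curves(path, guide), CrossSection(2.0, 4.62), layout)
    by_x = {round(r.centroid[0], 3): r.half_height for r in rects}
    assert by_x[20.0] == pytest.approx(3.0)      # at the hole center
    assert by_x[12.0] == pytest.approx(2.31)     # beyond k > D/2
    assert by_x[28.0] == pytest.approx(2.31)


def test_sweep_end_zones_follow_disc_circle():
    n = 81
    path = np.stack([np.linspace(0, 40, n), np.zeros(n), np.zeros(n)], axis=1)
    guide = path + [0, 0, 2]
    layout = HoleLayout(
        centers=[np.array([3.0, 0, 0]), np.array([37.0, 0, 0])], boss_diameter=6.0
    )
    rects = sweep(_curves(path, guide), CrossSection(2.0, 4.62), layout)
    for r in rects:
        x = r.centroid[0]
        if x < 3.0:  # start end zone
            k = 3.0 - x
            assert r.half_height == pytest.approx(np.sqrt(9.0 - k * k), abs=1e-9)


def test_half_height_profile_continuity_refines_with_pitch():
    def max_jump(n):
        path = np.stack([np.linspace(0, 40, n), np.zeros(n), np.zeros(n)], axis=1)
        guide = path + [0, 0, 2]
        layout = HoleLayout(
            centers=[np.array([3.0, 0, 0]), np.array([20.0, 0, 0]), np.array([37.0, 0, 0])],
            boss_diameter=6.0,
        )
        rects = sweep(_curves(path, guide), CrossSection(2.0, 4.62), layout)
        hh = np.array([r.half_height for r in rects])
        return np.abs(np.diff(hh)).max()

    assert max_jump(321) < max_jump(81)
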