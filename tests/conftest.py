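"""Shared fixtures: tiny analytic meshes and one moderately sized designed plate.

Everything is generated at test time; the plate build is session-scoped
because the Boolean stage dominates runtime.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from psiplate import (
    PlateConfig,
    TriangleMesh,
    design_plate,
    make_bone,
    make_plan,
)


def make_box(sx: float, sy: float, sz: float, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned box with outward-oriented triangles."""
    c = np.asarray(center, dtype=float)
    verts = (
        np.array(list(itertools.product([-sx / 2, sx / 2], [-sy / 2, sy / 2], [-sz / 2, sz / 2])))
        + c
    )
    # index pattern: bit0 -> z, bit1 -> y, bit2 -> x
    quads = [
        (0, 1, 3, 2),  # x = -sx/2
        (4, 6, 7, 5),  # x = +sx/2
        (0, 4, 5, 1),  # y = -sy/2
        (2, 3, 7, 6),  # y = +sy/2
        (0, 2, 6, 4),  # z = -sz/2
        (1, 5, 7, 3),  # z = +sz/2
    ]
    faces = []
    centroid = verts.mean(axis=0)
    for q in quads:
        for tri in ((q[0], q[1], q[2]), (q[0], q[2], q[3])):
            a, b, cc = verts[list(tri)]
            n = np.cross(b - a, cc - a)
            faces.append(tri if n @ (a - centroid) > 0 else tri[::-1])
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def make_tetrahedron() -> TriangleMesh:
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(verts, faces)


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    return make_tetrahedron()


@pytest.fixture(scope="session")
def test_config() -> PlateConfig:
    """Paper-default plate geometry at test-friendly discretization."""
    cfg = PlateConfig(sample_pitch_mm=0.8)
    cfg.hole.segments = 32
    return cfg


@pytest.fixture(scope="session")
def demo_bone() -> TriangleMesh:
    return make_bone(seed=3)


@pytest.fixture(scope="session")
def demo_plan(demo_bone):
    return make_plan(demo_bone, n_points=8, n_holes=3, seed=3)


@pytest.fixture(scope="session")
def designed_plate(demo_plan, demo_bone, test_config):
    """Full pipeline output: (plate mesh, report); 5 screw holes."""
    return design_plate(demo_plan, test_config, bone=demo_bone)
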