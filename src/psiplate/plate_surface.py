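"""Skin the ordered surviving rectangles into a closed triangulated surface.

Corner j of section n joins corner j of section n+1 (roll continuity from
the sweep guarantees no flips on smooth paths); each of the four side-wall
quads is split into two triangles along its shorter diagonal, and the first
and last sections are capped.  The corner loops are CCW about the travel
direction, which fixes a consistent outward winding for walls and caps.
"""

from __future__ import annotations

import numpy as np

from .errors import SkinningError
from .mesh_io import TriangleMesh, merge_duplicate_vertices
from .sweep_engine import PlacedRectangle


def skin(rects: list[PlacedRectangle]) -> TriangleMesh:
    """Watertight genus-0 surface through the ordered cross-sections."""
    if len(rects) < 2:
        raise SkinningError("skinning needs at least 2 sections")
    corners = np.stack([r.corners if isinstance(r, PlacedRectangle) else np.asarray(r)
                        for r in rects])  # (N, 4, 3)
    n_sec = len(corners)
    verts = corners.reshape(-1, 3)
    faces: list[tuple[int, int, int]] = []

    def vid(sec: int, corner: int) -> int:
        return 4 * sec + (corner % 4)

    # walls
    for s in range(n_sec - 1):
        a, b = corners[s], corners[s + 1]
        for j in range(4):
            j2 = (j + 1) % 4
            # flipped correspondence makes the wall quad a bowtie
            if (a[j2] - a[j]) @ (b[j2] - b[j]) < 0:
                raise SkinningError(
                    f"corner correspondence flip between sections {s} and {s + 1}"
                )
            d1 = np.linalg.norm(a[j] - b[j2])
            d2 = np.linalg.norm(a[j2] - b[j])
            if d1 <= d2:  # diagonal a[j]–b[j2]
                faces.append((vid(s, j), vid(s, j2), vid(s + 1, j2)))
                faces.append((vid(s, j), vid(s + 1, j2), vid(s + 1, j)))
            else:  # diagonal a[j2]–b[j]
                faces.append((vid(s, j), vid(s, j2), vid(s + 1, j)))
                faces.append((vid(s, j2), vid(s + 1, j2), vid(s + 1, j)))
    # caps: start cap wound CW about travel (outward −v̂), end cap CCW (+v̂)
    faces.append((vid(0, 0), vid(0, 2), vid(0, 1)))
    faces.append((vid(0, 0), vid(0, 3), vid(0, 2)))
    last = n_sec - 1
    faces.append((vid(last, 0), vid(last, 1), vid(last, 2)))
    faces.append((vid(last, 0), vid(last, 2), vid(last, 3)))

    v, f = merge_duplicate_vertices(verts, np.array(faces, dtype=np.int64), tol=1e-9)
    mesh = TriangleMesh(v, f)
    mesh.validate()
    return mesh
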