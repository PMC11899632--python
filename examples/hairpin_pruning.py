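"""Show the separating-axis pruning rescuing a too-tight hairpin path.

A 180-degree bend tighter than the cross-section makes inner-bend sections
cross each other; the pruner removes the worst offenders until the
survivors are pairwise disjoint, so skinning cannot fold the surface.
"""

import numpy as np

from psiplate import (
    CrossSection,
    HoleLayout,
    TraceCurvePair,
    prune,
    rectangles_intersect,
    sweep,
)

t = np.linspace(0, np.pi, 60)
r_bend = 1.5  # mm, tighter than the 4.62 mm in-plane section used below
path = np.stack(
    [np.concatenate([np.linspace(-6, 0, 20)[:-1], r_bend * np.sin(t), np.linspace(0, -6, 20)[1:]]),
     np.concatenate([np.full(19, -r_bend), -r_bend * np.cos(t), np.full(19, r_bend)]),
     np.zeros(60 + 38)],
    axis=1,
)
curves = TraceCurvePair(path, path + [0.0, 0.0, 2.0], 0, 1.0)
rects = sweep(curves, CrossSection(4.62, 2.0), HoleLayout())
report = prune(rects)

print(f"sections:               {len(rects)}")
print(f"intersecting pairs:     {len(report.pairs)}")
print(f"sections removed:       {len(report.removed)} -> {report.removed}")
survivors = [rects[i] for i in report.survivors]
clean = all(
    not rectangles_intersect(survivors[i], survivors[j])
    for i in range(len(survivors))
    for j in range(i + 2, len(survivors))
)
print(f"survivors pairwise disjoint (beyond adjacency): {clean}")
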