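"""Solve mandible reactions for the literature muscle table and scale it.

Uses the packaged twelve-muscle right-molar-clenching force table (with
synthetic attachment coordinates) and plausible tooth/condyle points.  The
tooth reaction magnitude then scales every muscle force to a measured 91 N
bite; the joint/tooth ratio summarizes how load splits between the
temporomandibular joints and the tooth contact.
"""

import numpy as np

from psiplate import (
    joint_tooth_ratio,
    load_reference_muscles,
    scale_muscle_forces,
    solve_reactions,
    synthetic_reaction_geometry,
)

muscles = load_reference_muscles()
geom = synthetic_reaction_geometry()  # alpha 100 deg, beta 70 deg, gamma 90 deg

sol = solve_reactions(muscles, geom)
for name, vec in (("T ", sol.T), ("CL", sol.CL), ("CR", sol.CR)):
    print(f"{name} = [{vec[0]:9.2f} {vec[1]:9.2f} {vec[2]:9.2f}] N  "
          f"|{name.strip()}| = {np.linalg.norm(vec):8.2f} N")
print(f"joint/tooth ratio (this synthetic geometry): {joint_tooth_ratio(sol):.2f}")
print(f"equilibrium residuals: F {sol.force_residual:.2e} N, "
      f"M {sol.moment_residual:.2e} N*mm")

scaled, s = scale_muscle_forces(muscles, sol.T_mag, measured_bite=91.0)
print(f"\nscale s = 91 / {sol.T_mag:.2f} = {s:.4f}")
ilpr = next(m for m in scaled if m.name == "ILPR")
print(f"scaled ILPR force: [{ilpr.force[0]:.2f} {ilpr.force[1]:.2f} {ilpr.force[2]:.2f}] N")
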