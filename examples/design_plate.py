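"""Design a fixation plate for a synthetic curved bone and export an STL.

Builds a mandible-like tube, lays surgeon-style picks on its outer surface,
runs the full pipeline (trace curves -> sweep -> pruning -> skinning ->
countersunk holes -> Boolean), and prints the printability diagnostics.
The Euler characteristic 2 - 2k confirms one handle per screw hole.
"""

from psiplate import design_plate, make_bone, make_plan, write_stl

bone = make_bone(length=80.0, curvature_radius=60.0, cross_radius=6.0, seed=7)
plan = make_plan(bone, n_points=8, n_holes=3, seed=7)

plate, report = design_plate(plan, bone=bone)
write_stl(plate, "plate.stl", dialect="ascii")

d = report["diagnostics"]
print(f"path samples:        {report['stages']['trace_curves']['path_samples']}")
print(f"screw holes:         {report['stages']['holes']['n_holes']} "
      f"(2 auto end holes + {report['stages']['holes']['n_manual']} picked)")
print(f"sections swept:      {report['stages']['sweep']['sections']}")
print(f"sections pruned:     {len(report['stages']['prune']['removed'])}")
print(f"triangles:           {d['triangle_count']}")
print(f"watertight:          {d['is_watertight']}")
print(f"Euler characteristic {d['euler_characteristic']} "
      f"(expected {report['expected_euler_characteristic']})")
print("wrote plate.stl")
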