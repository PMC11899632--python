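"""End-to-end plate design: plan + bone in, printable plate mesh out.

Stages run in fixed order — trace curves, hole placement, sweep, overlap
pruning, skinning, hole meshing, Boolean subtraction — and the run is fully
deterministic: identical inputs and configuration give byte-identical STL
output.  A JSON-serializable report collects per-stage counts, pruning
decisions, diagnostics and timings.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict

from .config import PlateConfig
from .hole_model import HoleSpec, hole_meshes_for, place_holes
from .mesh_boolean import subtract
from .mesh_io import TriangleMesh, diagnose
from .overlap_pruning import prune
from .plate_surface import skin
from .sweep_engine import CrossSection, HoleLayout, sweep
from .trace_curves import PlanPoints, build_trace_curves

log = logging.getLogger(__name__)


def design_plate(
    plan: PlanPoints,
    config: PlateConfig | None = None,
    bone: TriangleMesh | None = None,
) -> tuple[TriangleMesh, dict]:
    """Run the whole design pipeline; returns (plate mesh, report).

    The bone mesh, when given, is only validated and described in the
    report — the plan points are trusted to lie on its surface already.
    """
    config = config or PlateConfig()
    report: dict = {"config": config.to_dict(), "stages": {}}
    t_start = time.perf_counter()

    def stage(name: str):
        report["stages"][name] = {"t_start_s": round(time.perf_counter() - t_start, 4)}
        return report["stages"][name]

    if bone is not None:
        info = stage("bone")
        bone.validate()
        d = diagnose(bone)
        info.update(triangles=d.triangle_count, watertight=d.is_watertight)

    info = stage("trace_curves")
    curves = build_trace_curves(plan, pitch_mm=config.sample_pitch_mm)
    info.update(path_samples=len(curves.path))

    info = stage("holes")
    layout = HoleLayout(
        screw_diameter=config.screw_diameter_mm,
        boss_diameter=config.boss_diameter_mm,
    )
    holes, layout = place_holes(plan.P1, curves, layout)
    info.update(n_holes=len(holes), n_manual=len(plan.P1))

    info = stage("sweep")
    section = CrossSection(thickness=config.thickness_mm, width=config.width_mm)
    rects = sweep(curves, section, layout)
    info.update(sections=len(rects))

    info = stage("prune")
    pr = prune(rects)
    rects = [rects[i] for i in pr.survivors]
    info.update(pr.to_dict())

    info = stage("skin")
    plate = skin(rects)
    info.update(triangles=len(plate.faces))

    info = stage("boolean")
    spec = HoleSpec(
        shaft_diameter=config.hole.phi_mm,
        head_diameter=config.hole.head_diameter_mm,
        head_angle_deg=config.hole.head_angle_deg,
        height=config.thickness_mm + 2 * config.hole.overshoot_mm,
        segments=config.hole.segments,
    )
    cutters = hole_meshes_for(
        holes, config.thickness_mm, spec=spec, overshoot=config.hole.overshoot_mm
    )
    plate = subtract(plate, cutters)
    d = diagnose(plate)
    info.update(triangles=d.triangle_count)

    report["diagnostics"] = asdict(d)
    report["elapsed_s"] = round(time.perf_counter() - t_start, 4)
    report["ok"] = bool(d.is_watertight and d.is_consistently_oriented)
    expected_chi = 2 - 2 * len(holes)
    report["expected_euler_characteristic"] = expected_chi
    if d.euler_characteristic != expected_chi:
        log.warning(
            "Euler characteristic %d differs from expected %d for %d holes",
            d.euler_characteristic, expected_chi, len(holes),
        )
    return plate, report
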