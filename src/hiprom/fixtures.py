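"""Synthetic implant fixtures.

No proprietary implant geometry ships with this package; these parametric
implants stand in for commercial stems (synthetic by construction, labelled
so).  The trapezoidal family mirrors the geometry that drives the published
phenomena: a neck that is narrowest just distal to the trunnion and widens
toward the shoulder (full widths ~11-21 mm, matching the span reported for
modern trapezoidal stems), a trunnion frustum wider than the distal neck so
extra-long heads impinge on it, modular heads of 28-40 mm diameter and
offsets -4 to +8 mm, and hemispherical liners congruent with each head.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .config import implant_to_dict
from .implants import (
    DEFAULT_RESOLUTION,
    HeadSpec,
    ImplantAssembly,
    LinerSpec,
    NeckProfile,
    StemSpec,
    make_assembly,
)

__all__ = [
    "HEAD_DIAMETERS_MM",
    "HEAD_OFFSETS_MM",
    "cylindrical_assembly",
    "trapezoidal_stem",
    "trapezoidal_assembly",
    "worst_case_assembly",
    "hemispherical_liner",
    "make_fixtures",
]

HEAD_DIAMETERS_MM = (28.0, 32.0, 36.0, 40.0)
HEAD_OFFSETS_MM = (-4.0, 0.0, 4.0, 8.0)


def hemispherical_liner(head_radius_mm: float) -> LinerSpec:
    """Liner congruent with the head: cavity depth equal to its radius."""
    return LinerSpec(
        inner_radius_mm=head_radius_mm,
        depth_mm=head_radius_mm,
        rim_outer_radius_mm=head_radius_mm + 5.0,
    )


def cylindrical_assembly(
    head_diameter_mm: float = 32.0,
    neck_width_mm: float = 12.0,
    offset_mm: float = 0.0,
    resolution: int = DEFAULT_RESOLUTION,
) -> ImplantAssembly:
    """Constant-width circular neck (trunnion flush): the reference geometry
    for which the cone-overlap formula is exact."""
    stem = StemSpec(neck=NeckProfile.cylindrical(neck_width_mm))
    head = HeadSpec(radius_mm=head_diameter_mm / 2.0, offset_mm=offset_mm)
    return make_assembly(
        stem, head, hemispherical_liner(head.radius_mm), resolution
    )


def trapezoidal_stem() -> StemSpec:
    """The synthetic trapezoidal-neck stem used across the parameter studies."""
    profile = NeckProfile(
        kind="trapezoidal",
        neck_length_mm=24.0,
        ap_width_junction_mm=12.0,
        ap_width_base_mm=18.0,
        pd_width_junction_mm=11.0,
        pd_width_base_mm=20.6,
        corner_radius_mm=2.0,
        # trunnion + skirt of the extra-long head: clearly wider than the
        # distal neck so engaging it visibly costs range of motion
        trunnion_diameter_mm=16.0,
        trunnion_length_mm=4.0,
        trunnion_tip_offset_mm=4.0,
        trunnion_taper_mm=0.5,
    )
    return StemSpec(neck=profile, neck_shaft_angle_deg=125.0,
                    supported_offsets_mm=HEAD_OFFSETS_MM)


def trapezoidal_assembly(
    head_diameter_mm: float = 32.0,
    offset_mm: float = 0.0,
    resolution: int = DEFAULT_RESOLUTION,
) -> ImplantAssembly:
    head = HeadSpec(radius_mm=head_diameter_mm / 2.0, offset_mm=offset_mm)
    return make_assembly(
        trapezoidal_stem(), head, hemispherical_liner(head.radius_mm),
        resolution,
    )


def worst_case_assembly(resolution: int = DEFAULT_RESOLUTION) -> ImplantAssembly:
    """Largest fixture head engaged at the shortest offset: impingement lands
    closest to the stem shoulder, where the neck geometry varies fastest, so
    the interpolated model is least accurate here."""
    return trapezoidal_assembly(
        head_diameter_mm=max(HEAD_DIAMETERS_MM),
        offset_mm=min(HEAD_OFFSETS_MM),
        resolution=resolution,
    )


def make_fixtures(out_dir) -> list[Path]:
    """Write the synthetic implant configs (YAML) to a directory.

    Regeneration is byte-identical: specs are static and keys are sorted.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def entry(stem, head):
        return stem, head, hemispherical_liner(head.radius_mm)

    cyl = StemSpec(neck=NeckProfile.cylindrical(12.0))
    trap = trapezoidal_stem()
    entries = {
        "cylindrical_reference": entry(cyl, HeadSpec(16.0)),
    }
    for d in HEAD_DIAMETERS_MM:
        entries[f"trapezoidal_head{d:.0f}"] = entry(trap, HeadSpec(d / 2.0))
    for off in HEAD_OFFSETS_MM:
        entries[f"trapezoidal_offset{off:+.0f}"] = entry(
            trap, HeadSpec(16.0, offset_mm=off)
        )
    entries["worst_case_validation"] = entry(
        trap,
        HeadSpec(max(HEAD_DIAMETERS_MM) / 2.0, offset_mm=min(HEAD_OFFSETS_MM)),
    )
    paths = []
    for name, (stem, head, liner) in entries.items():
        cfg = implant_to_dict(stem, head, liner)
        path = out / f"{name}.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        paths.append(path)
    return paths
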