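"""Structured configuration: implant YAML/JSON files, run config, targets.

All angle and length I/O is in degrees and millimetres.  Unknown keys are
rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .implants import (
    DEFAULT_RESOLUTION,
    HeadSpec,
    ImplantAssembly,
    LinerSpec,
    NeckProfile,
    StemSpec,
    make_assembly,
)
from .rom import ROMTarget

__all__ = [
    "parse_target",
    "implant_to_dict",
    "implant_from_dict",
    "load_implant",
    "RunConfig",
    "load_run_config",
]

_TARGET_RE = re.compile(
    r"^\s*([0-9.]+)\s*°?\s*IR\s*@\s*([0-9.]+)\s*°?\s*FL\s*,"
    r"\s*([0-9.]+)\s*°?\s*ER\s*@\s*([0-9.]+)\s*°?\s*EX\s*$",
    re.IGNORECASE,
)


def parse_target(text: str) -> ROMTarget:
    """Parse "<ir>IR@<fl>FL,<er>ER@<ex>EX" (whitespace-tolerant)."""
    m = _TARGET_RE.match(text)
    if m is None:
        raise ValueError(
            f"malformed ROM target {text!r}; expected e.g. '30IR@90FL,10ER@10EX'"
        )
    ir, fl, er, ex = (float(g) for g in m.groups())
    return ROMTarget(ir_deg=ir, fl_deg=fl, er_deg=er, ex_deg=ex)


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def implant_to_dict(stem: StemSpec, head: HeadSpec, liner: LinerSpec) -> dict:
    return {
        "stem": {
            "neck_shaft_angle_deg": stem.neck_shaft_angle_deg,
            "supported_offsets_mm": list(stem.supported_offsets_mm),
            "neck": asdict(stem.neck),
        },
        "head": asdict(head),
        "liner": asdict(liner),
    }


def implant_from_dict(cfg: dict) -> tuple[StemSpec, HeadSpec, LinerSpec]:
    _check_keys(cfg, {"stem", "head", "liner"}, "implant config")
    stem_cfg = dict(cfg["stem"])
    _check_keys(
        stem_cfg, {"neck_shaft_angle_deg", "supported_offsets_mm", "neck"},
        "stem",
    )
    neck = NeckProfile(**stem_cfg.pop("neck"))
    stem = StemSpec(
        neck=neck,
        neck_shaft_angle_deg=stem_cfg.get("neck_shaft_angle_deg", 125.0),
        supported_offsets_mm=tuple(
            stem_cfg.get("supported_offsets_mm", (-4.0, 0.0, 4.0, 8.0))
        ),
    )
    head = HeadSpec(**cfg["head"])
    liner = LinerSpec(**cfg["liner"])
    return stem, head, liner


def load_implant(path, resolution: int = DEFAULT_RESOLUTION) -> ImplantAssembly:
    """Build an assembly from a YAML (or JSON) implant file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    stem, head, liner = implant_from_dict(cfg)
    return make_assembly(stem, head, liner, resolution)


@dataclass
class RunConfig:
    """End-to-end run configuration with the model's default placement."""

    implant: str = ""
    target: str = "30IR@90FL,10ER@10EX"
    neck_shaft_angle_deg: float = 125.0
    stem_flexion_deg: float = 0.0
    stem_adduction_deg: float = 6.0
    stem_anteversion_deg: float = 0.0
    db_slices: list = field(
        default_factory=lambda: [-40.0, -20.0, 0.0, 20.0, 40.0, 60.0]
    )
    db_grid_step_deg: float = 10.0
    map_step_deg: float = 1.0
    boundary_alpha_step_deg: float = 2.0
    mesh_resolution: int = DEFAULT_RESOLUTION
    bisect_tol_deg: float = 0.05
    out_dir: str = "out"
    seed: int | None = None  # randomized fixtures only; the pipeline is deterministic

    def rom_target(self) -> ROMTarget:
        return parse_target(self.target)


def load_run_config(path) -> RunConfig:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(RunConfig.__dataclass_fields__)
    _check_keys(cfg, allowed, "run config")
    rc = RunConfig(**cfg)
    # parse-validate round trip: the target must parse and re-render stably
    rc.rom_target()
    return rc


def dump_run_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
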