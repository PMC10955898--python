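"""Run configuration: TOML-backed, validated, serialized for provenance."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .simulate import DetectorModel, ScanConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """End-to-end run parameters.

    Units are fixed: mm (lengths), us (times), MHz (frequencies).
    Sections in TOML: [code], [scan], [detector], [phantom], [recon].
    """

    P: int = 41
    Q: int = 43
    aperture_diameter: float = 0.5
    scan: ScanConfig = field(default_factory=ScanConfig)
    detector: DetectorModel = field(default_factory=DetectorModel)
    phantom_kind: str = "point"
    phantom_params: dict = field(default_factory=dict)
    voxel_size: float = 0.1
    box_half_extent: float = 2.0
    output: str = "run.h5"

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        code = raw.get("code", {})
        kwargs: dict = {}
        if "P" in code:
            kwargs["P"] = int(code["P"])
        if "Q" in code:
            kwargs["Q"] = int(code["Q"])
        if "aperture_diameter" in code:
            kwargs["aperture_diameter"] = float(code["aperture_diameter"])
        if "scan" in raw:
            kwargs["scan"] = ScanConfig(**raw["scan"])
        if "detector" in raw:
            kwargs["detector"] = DetectorModel(**raw["detector"])
        ph = raw.get("phantom", {})
        if ph:
            kwargs["phantom_kind"] = ph.pop("kind", "point")
            kwargs["phantom_params"] = ph
        rec = raw.get("recon", {})
        if "voxel_size" in rec:
            kwargs["voxel_size"] = float(rec["voxel_size"])
        if "box_half_extent" in rec:
            kwargs["box_half_extent"] = float(rec["box_half_extent"])
        if "output" in raw.get("io", {}):
            kwargs["output"] = raw["io"]["output"]
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
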