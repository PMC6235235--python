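"""Run configuration: a flat YAML schema resolved and re-emitted per run.

Every CLI run writes its fully resolved configuration (including the seed)
next to its outputs, so any run is reproducible from that file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .grids import ValidationError
from .segmentation import SegmentationParams


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spacing_override: tuple[float, float, float] | None = None
    positioning_method: str = "crosscorr"
    positioning_max_shift: float = 5000.0
    psf_smooth_sigma: float = 1.0
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        from .io import atomic_write  # local import: io depends on segmentation types

        doc = asdict(self)
        doc["segmentation"] = asdict(self.segmentation)
        atomic_write(path, lambda tmp: Path(tmp).write_text(yaml.safe_dump(doc, sort_keys=True)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ValidationError(f"{path} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        seg = doc.pop("segmentation", {})
        if seg is not None and not isinstance(seg, dict):
            raise ValidationError("'segmentation' must be a mapping")
        seg_known = {f.name for f in fields(SegmentationParams)}
        seg_unknown = set(seg or {}) - seg_known
        if seg_unknown:
            raise ValidationError(f"unknown segmentation keys: {sorted(seg_unknown)}")
        if doc.get("spacing_override") is not None:
            doc["spacing_override"] = tuple(float(v) for v in doc["spacing_override"])
        return cls(segmentation=SegmentationParams(**(seg or {})), **doc)
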