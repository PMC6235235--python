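"""Voxel grid container: a 3D intensity stack with physical voxel spacing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Invalid parameters or malformed inputs (exit code 2 at the CLI)."""


class DataError(RuntimeError):
    """Well-formed request but unusable data (exit code 3 at the CLI)."""


@dataclass
class VoxelGrid:
    """3D fluorescence stack indexed (z, y, x) with voxel spacing in micrometres.

    Axis convention follows the instrument: x is the flow / anterior-posterior
    axis, z the detection (scan) axis.  ``spacing`` is (dz, dy, dx) in μm so
    that ``spacing[i]`` matches ``data.shape[i]``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = field(default=(2.5, 0.325, 0.325))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D stack, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"voxel spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in μm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in μm."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))
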