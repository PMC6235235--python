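"""Instrument geometry and flow arithmetic.

Small closed-form helpers for the numbers that characterize the fluidic
light-sheet setup: the physical volume of one 3D scan and the mean flow
speed of specimens through the transport tubing.
"""

from __future__ import annotations

import math

from .grids import ValidationError

# One full scan covers 666 × 431 × 1060 μm in (x, y, z).
SCAN_EXTENT_UM = (666.0, 431.0, 1060.0)
# Specimens travel through 0.7 mm inner-diameter tubing at 1 ml/min.
TUBING_INNER_DIAMETER_MM = 0.7
FLOW_RATE_ML_PER_MIN = 1.0


def scan_volume_mm3(extent_um: tuple[float, float, float] = SCAN_EXTENT_UM) -> float:
    """Volume of one rectangular scan in mm³ (1 mm³ = 1e9 μm³)."""
    if any(e <= 0 for e in extent_um):
        raise ValidationError("scan extents must be positive")
    x, y, z = extent_um
    return x * y * z * 1e-9


def flow_speed_cm_per_s(
    flow_ml_per_min: float = FLOW_RATE_ML_PER_MIN,
    inner_diameter_mm: float = TUBING_INNER_DIAMETER_MM,
) -> float:
    """Mean flow speed in cm/s from a volumetric rate through round tubing."""
    if flow_ml_per_min <= 0 or inner_diameter_mm <= 0:
        raise ValidationError("flow rate and tubing diameter must be positive")
    radius_cm = inner_diameter_mm / 10.0 / 2.0
    area_cm2 = math.pi * radius_cm**2
    return (flow_ml_per_min / 60.0) / area_cm2
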