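"""Point-spread-function estimation from fluorescent bead stacks.

Optical resolution is characterized by imaging sub-resolution fluorescent
microspheres and fitting a Gaussian A·exp(−(u−u₀)²/2σ²) + B to single-voxel
line scans through the bead along each axis.  The reported "width" is the
Gaussian standard deviation σ, not the FWHM (multiply by 2·√(2·ln2) ≈ 2.355
for FWHM).  For a light sheet, σz reflects the sheet thickness and is
typically several-fold larger than the in-plane σx, σy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .grids import DataError, ValidationError, VoxelGrid

_HWHM_TO_SIGMA = np.sqrt(2.0 * np.log(2.0))  # HWHM = sigma * 1.177...


@dataclass
class GaussianFit:
    """Least-squares Gaussian-plus-baseline fit to one line scan."""

    sigma: float
    center: float
    amplitude: float
    baseline: float
    residual_rms: float


@dataclass
class PSFEstimate:
    """Per-axis Gaussian widths of the point spread function.

    sigma is (σx, σy, σz) in μm; center is the bead position (x, y, z) in μm;
    residual_rms is the worst per-axis fit residual.
    """

    sigma: tuple[float, float, float]
    center: tuple[float, float, float]
    amplitude: float
    baseline: float
    residual_rms: float


def locate_bead(grid: VoxelGrid, smooth_sigma_voxels: float = 1.0) -> tuple[int, int, int]:
    """Voxel index (z, y, x) of the global maximum after light smoothing.

    Ties break to the raster-first voxel.  A flat stack has no bead.
    """
    data = grid.data.astype(np.float64)
    if data.max() == data.min():
        raise DataError("stack is flat: no bead to locate")
    if smooth_sigma_voxels > 0:
        data = ndimage.gaussian_filter(data, smooth_sigma_voxels)
    idx = np.unravel_index(int(np.argmax(data)), data.shape)
    return tuple(int(i) for i in idx)


def _gauss(u: np.ndarray, amplitude: float, center: float, sigma: float, baseline: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((u - center) / sigma) ** 2) + baseline


def fit_gaussian_profile(line: np.ndarray, step: float) -> GaussianFit:
    """Fit A·exp(−(u−u₀)²/2σ²) + B to a 1D line scan sampled every ``step`` μm.

    Initialization: A = max−min, B = min, u₀ at the maximum, σ from the
    half-width at half-maximum (HWHM / 1.177) — a robust derivative-free
    start.  Raises on constant lines or non-convergence.
    """
    line = np.asarray(line, dtype=np.float64)
    if line.ndim != 1 or line.size < 5:
        raise ValidationError("line scan must be 1D with at least 5 samples")
    if step <= 0:
        raise ValidationError("step must be positive")
    if line.max() == line.min():
        raise DataError("constant line scan: nothing to fit")
    u = np.arange(line.size) * step
    a0 = line.max() - line.min()
    b0 = line.min()
    c0 = u[int(np.argmax(line))]
    half = b0 + a0 / 2.0
    above = np.flatnonzero(line > half)
    hwhm = max(step, 0.5 * (u[above[-1]] - u[above[0]])) if above.size else step
    s0 = max(hwhm / _HWHM_TO_SIGMA, step / 4.0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            u,
            line,
            p0=(a0, c0, s0, b0),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise DataError(
            f"Gaussian fit did not converge (init A={a0:.3g}, u0={c0:.3g}, "
            f"sigma={s0:.3g}, B={b0:.3g}): {exc}"
        ) from exc
    amplitude, center, sigma, baseline = popt
    sigma = abs(float(sigma))
    if sigma <= 0 or not np.isfinite(sigma):
        raise DataError(f"Gaussian fit returned unusable sigma={sigma}")
    resid = line - _gauss(u, *popt)
    return GaussianFit(
        sigma=sigma,
        center=float(center),
        amplitude=float(amplitude),
        baseline=float(baseline),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_psf(grid: VoxelGrid, smooth_sigma_voxels: float = 1.0, line_halfwidth: int = 0) -> PSFEstimate:
    """Estimate (σx, σy, σz) from a single-bead stack.

    Locates the bead, extracts axis-aligned line scans through it (single
    voxel wide by default; ``line_halfwidth`` > 0 averages over a
    (2h+1)²-voxel cross-section), and fits each scan independently.  Beads
    on a stack face give truncated profiles and are rejected.
    """
    iz, iy, ix = locate_bead(grid, smooth_sigma_voxels)
    nz, ny, nx = grid.shape
    if iz in (0, nz - 1) or iy in (0, ny - 1) or ix in (0, nx - 1):
        raise DataError(f"bead at voxel ({iz},{iy},{ix}) touches a stack face; profile truncated")
    dz, dy, dx = grid.spacing
    h = int(line_halfwidth)

    def line_along(axis: int) -> np.ndarray:
        sl = [slice(max(0, i - h), i + h + 1) for i in (iz, iy, ix)]
        sl[axis] = slice(None)
        patch = grid.data[tuple(sl)]
        axes = tuple(a for a in range(3) if a != axis)
        return patch.mean(axis=axes)

    fit_z = fit_gaussian_profile(line_along(0), dz)
    fit_y = fit_gaussian_profile(line_along(1), dy)
    fit_x = fit_gaussian_profile(line_along(2), dx)
    return PSFEstimate(
        sigma=(fit_x.sigma, fit_y.sigma, fit_z.sigma),
        center=(fit_x.center, fit_y.center, fit_z.center),
        amplitude=float(np.mean([fit_x.amplitude, fit_y.amplitude, fit_z.amplitude])),
        baseline=float(np.mean([fit_x.baseline, fit_y.baseline, fit_z.baseline])),
        residual_rms=float(max(fit_x.residual_rms, fit_y.residual_rms, fit_z.residual_rms)),
    )
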