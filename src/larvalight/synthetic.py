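"""Synthetic microscopy data with known ground truth.

Generates the four kinds of inputs the analysis modules consume:

* fluorescence stacks of sparse bright ellipsoidal cells (GFP-expressing
  neutrophils) over autofluorescent background, blurred by an anisotropic
  Gaussian PSF, with Poisson or Gaussian noise;
* bead stacks: a single sub-resolution point source imaged through the PSF;
* 1D brightfield intensity profiles with strong minima emulating the eyes
  and swim bladder of a larval zebrafish;
* per-fish cohort tables (neutrophil count, total fluorescence intensity,
  anterior-posterior cell positions).

Every generator is fully determined by its recipe plus seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .grids import ValidationError, VoxelGrid
from .cohort import FishRecord
from .positioning import IntensityProfile

# Default instrument conditions: z step 2.5 μm per slice; in-plane pixel pitch
# inferred as 666 μm field width / 2048 sensor pixels = 0.325 μm (configurable,
# the in-plane pitch is an inference, not a measured number).
DEFAULT_SPACING = (2.5, 0.325, 0.325)
# Measured optical resolution: in-sheet-plane sigma 0.6 μm, detection-axis
# sigma 3.4 μm (sheet thickness).
DEFAULT_PSF_SIGMA = (0.6, 0.6, 3.4)


@dataclass
class BlobSpec:
    """One synthetic cell: anisotropic Gaussian intensity blob.

    ``center`` and ``radii`` are (x, y, z) in μm; ``radii`` are the Gaussian
    standard deviations of the unblurred cell along each axis.
    ``peak_intensity`` is the unblurred peak in arbitrary fluorescence units.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    peak_intensity: float

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        self.radii = tuple(float(r) for r in self.radii)
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValidationError("center and radii must be (x, y, z) triples")
        if any(r <= 0 for r in self.radii):
            raise ValidationError(f"blob radii must be positive, got {self.radii}")
        if self.peak_intensity <= 0:
            raise ValidationError(f"peak_intensity must be positive, got {self.peak_intensity}")

    @property
    def integral(self) -> float:
        """Total (unblurred) intensity mass in units·μm³."""
        rx, ry, rz = self.radii
        return self.peak_intensity * (2 * np.pi) ** 1.5 * rx * ry * rz


@dataclass
class StackRecipe:
    """Full description of one synthetic fluorescence stack.

    noise_model: "none", "gaussian" (additive, sd = noise_param) or
    "poisson" (shot noise; noise_param is the camera gain, counts per
    intensity unit).  ``margin_sigmas`` requires each blob to sit that many
    radii from every stack face (avoids truncated-mass edge cases).
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    blobs: list[BlobSpec] = field(default_factory=list)
    background_level: float = 100.0
    background_texture_scale: float = 10.0
    background_texture_amplitude: float = 0.0
    psf_sigma: tuple[float, float, float] = DEFAULT_PSF_SIGMA
    noise_model: str = "poisson"
    noise_param: float = 1.0
    seed: int = 0
    margin_sigmas: float = 3.0
    # bright sub-cellular debris: (center_um_xyz, edge_voxels, added_intensity),
    # rendered as solid cubes after the PSF blur (they model unphysical
    # speckle — hot pixels, debris — that the volume filter must reject)
    speckles: list[tuple[tuple[float, float, float], int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(n < 4 for n in self.shape):
            raise ValidationError(f"stack shape must be at least (4,4,4), got {self.shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.background_level < 0:
            raise ValidationError("background_level must be non-negative")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in μm."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.voxel_spacing
        return (nx * dx, ny * dy, nz * dz)


@dataclass
class ProfileRecipe:
    """Synthetic brightfield intensity profile: a bright baseline with
    Gaussian-shaped dark dips at the positions of strong anatomical features
    (eyes, swim bladder).

    ``offset`` shifts the whole feature set along +x in μm; sub-sample shifts
    are realized by linear interpolation of the unshifted profile.
    """

    length: int = 512
    step: float = 3.0
    feature_positions: tuple[float, ...] = (300.0, 900.0)
    feature_depths: tuple[float, ...] = (0.6, 0.9)
    feature_width_um: float = 30.0
    baseline: float = 1000.0
    noise_sigma: float = 0.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValidationError("profile length must be >= 2")
        if self.step <= 0:
            raise ValidationError("profile step must be positive")
        self.feature_positions = tuple(float(p) for p in self.feature_positions)
        self.feature_depths = tuple(float(d) for d in self.feature_depths)
        if len(self.feature_positions) != len(self.feature_depths):
            raise ValidationError("feature_positions and feature_depths must pair up")
        if any(not (0 < d <= 1) for d in self.feature_depths):
            raise ValidationError("feature depths must lie in (0, 1]")
        extent = self.length * self.step
        if any(not (0 <= p < extent) for p in self.feature_positions):
            raise ValidationError(f"feature positions must lie in [0, {extent}) μm")


def _blob_field(recipe: StackRecipe) -> np.ndarray:
    """Sum of PSF-blurred Gaussian blobs, computed analytically.

    A Gaussian blob convolved with a Gaussian PSF is again a Gaussian with
    per-axis variance r² + σ_psf²; the blur preserves total mass, so the
    blurred peak is scaled by Π rᵢ/σ_eff,ᵢ.  Each blob is rendered only
    within a ±5σ_eff bounding box for speed.
    """
    nz, ny, nx = recipe.shape
    dz, dy, dx = recipe.voxel_spacing
    sx, sy, sz = recipe.psf_sigma
    out = np.zeros(recipe.shape, dtype=np.float64)
    for blob in recipe.blobs:
        cx, cy, cz = blob.center
        rx, ry, rz = blob.radii
        ex = np.hypot(rx, sx)
        ey = np.hypot(ry, sy)
        ez = np.hypot(rz, sz)
        peak = blob.peak_intensity * (rx / ex) * (ry / ey) * (rz / ez)
        # index ranges covering ±5 sigma along each axis
        iz0 = max(0, int(np.floor((cz - 5 * ez) / dz)))
        iz1 = min(nz, int(np.ceil((cz + 5 * ez) / dz)) + 1)
        iy0 = max(0, int(np.floor((cy - 5 * ey) / dy)))
        iy1 = min(ny, int(np.ceil((cy + 5 * ey) / dy)) + 1)
        ix0 = max(0, int(np.floor((cx - 5 * ex) / dx)))
        ix1 = min(nx, int(np.ceil((cx + 5 * ex) / dx)) + 1)
        z = (np.arange(iz0, iz1) * dz - cz) / ez
        y = (np.arange(iy0, iy1) * dy - cy) / ey
        x = (np.arange(ix0, ix1) * dx - cx) / ex
        g = np.exp(-0.5 * z[:, None, None] ** 2) * np.exp(-0.5 * y[None, :, None] ** 2) * np.exp(
            -0.5 * x[None, None, :] ** 2
        )
        out[iz0:iz1, iy0:iy1, ix0:ix1] += peak * g
    return out


def _check_blob_bounds(recipe: StackRecipe) -> None:
    extent_x, extent_y, extent_z = recipe.extent_um
    m = recipe.margin_sigmas
    for blob in recipe.blobs:
        cx, cy, cz = blob.center
        rx, ry, rz = blob.radii
        if not (0 <= cx < extent_x and 0 <= cy < extent_y and 0 <= cz < extent_z):
            raise ValidationError(
                f"blob center {blob.center} lies outside the stack extent "
                f"({extent_x:.1f}, {extent_y:.1f}, {extent_z:.1f}) μm"
            )
        if m > 0:
            if (
                cx < m * rx
                or cx > extent_x - m * rx
                or cy < m * ry
                or cy > extent_y - m * ry
                or cz < m * rz
                or cz > extent_z - m * rz
            ):
                raise ValidationError(
                    f"blob at {blob.center} closer than {m} radii to a stack face; "
                    "set margin_sigmas=0 to allow"
                )


def _apply_noise(image: np.ndarray, model: str, param: float, rng: np.random.Generator) -> np.ndarray:
    if model == "none":
        return image
    if model == "gaussian":
        return image + rng.normal(0.0, param, size=image.shape)
    # Poisson shot noise at camera gain `param` counts per intensity unit
    return rng.poisson(np.clip(image, 0, None) * param).astype(np.float64) / param


def make_neutrophil_stack(recipe: StackRecipe) -> tuple[VoxelGrid, list[BlobSpec]]:
    """Render a synthetic neutrophil stack and return it with its ground truth.

    The stack is background (plus optional smooth autofluorescent texture)
    plus the sum of PSF-blurred Gaussian blobs, with noise applied last.
    Identical recipe + seed give bit-identical voxels.
    """
    _check_blob_bounds(recipe)
    rng = np.random.default_rng(recipe.seed)
    image = np.full(recipe.shape, float(recipe.background_level))
    if recipe.background_texture_amplitude > 0:
        sig_vox = [recipe.background_texture_scale / s for s in recipe.voxel_spacing]
        texture = ndimage.gaussian_filter(rng.standard_normal(recipe.shape), sig_vox)
        sd = texture.std()
        if sd > 0:
            image += recipe.background_texture_amplitude * texture / sd
        np.clip(image, 0, None, out=image)
    image += _blob_field(recipe)
    for center, edge, intensity in recipe.speckles:
        cx, cy, cz = center
        dz, dy, dx = recipe.voxel_spacing
        iz, iy, ix = int(round(cz / dz)), int(round(cy / dy)), int(round(cx / dx))
        h0, h1 = edge // 2, edge - edge // 2
        sl = (
            slice(max(0, iz - h0), min(recipe.shape[0], iz + h1)),
            slice(max(0, iy - h0), min(recipe.shape[1], iy + h1)),
            slice(max(0, ix - h0), min(recipe.shape[2], ix + h1)),
        )
        image[sl] += intensity
    image = _apply_noise(image, recipe.noise_model, recipe.noise_param, rng)
    grid = VoxelGrid(image, recipe.voxel_spacing)
    return grid, list(recipe.blobs)


def make_bead_stack(
    sigma: tuple[float, float, float] = DEFAULT_PSF_SIGMA,
    spacing: tuple[float, float, float] = (0.5, 0.1625, 0.1625),
    shape: tuple[int, int, int] = (64, 64, 64),
    snr: float | None = None,
    seed: int = 0,
    amplitude: float = 1000.0,
    baseline: float = 0.0,
) -> VoxelGrid:
    """Image of a single sub-resolution bead: a Gaussian of the PSF's widths.

    ``sigma`` is (σx, σy, σz) in μm; ``spacing`` is (dz, dy, dx).  The default
    z spacing of 0.5 μm matches a bead-stack acquisition.  ``snr`` is peak
    amplitude over Gaussian noise sd; None means noise-free.
    """
    sx, sy, sz = (float(s) for s in sigma)
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise ValidationError(f"PSF sigma must be positive, got {sigma}")
    dz, dy, dx = (float(s) for s in spacing)
    if dz <= 0 or dy <= 0 or dx <= 0:
        raise ValidationError(f"spacing must be positive, got {spacing}")
    for s, d, name in ((sx, dx, "x"), (sy, dy, "y"), (sz, dz, "z")):
        if s < 0.25 * d:
            warnings.warn(
                f"PSF sigma_{name}={s} μm is under-sampled at spacing {d} μm",
                stacklevel=2,
            )
    nz, ny, nx = (int(n) for n in shape)
    z = (np.arange(nz) - nz // 2) * dz
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    g = (
        np.exp(-0.5 * (z / sz) ** 2)[:, None, None]
        * np.exp(-0.5 * (y / sy) ** 2)[None, :, None]
        * np.exp(-0.5 * (x / sx) ** 2)[None, None, :]
    )
    image = baseline + amplitude * g
    if snr is not None:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, amplitude / snr, size=image.shape)
    return VoxelGrid(image, (dz, dy, dx))


def make_brightfield_profile(recipe: ProfileRecipe) -> IntensityProfile:
    """Synthesize a 1D axial brightfield profile with dark anatomical features.

    The unshifted profile is baseline·(1 − Σ depthᵢ·exp(−(u−pᵢ)²/2w²));
    the recipe's ``offset`` is applied by linear interpolation (out-of-range
    samples take the baseline), then Gaussian noise of sd ``noise_sigma``.
    """
    u = np.arange(recipe.length) * recipe.step
    dips = np.zeros(recipe.length)
    w = recipe.feature_width_um
    for p, d in zip(recipe.feature_positions, recipe.feature_depths):
        dips += d * np.exp(-0.5 * ((u - p) / w) ** 2)
    values = recipe.baseline * (1.0 - dips)
    if recipe.offset != 0.0:
        values = np.interp(u - recipe.offset, u, values, left=recipe.baseline, right=recipe.baseline)
    if recipe.noise_sigma > 0:
        rng = np.random.default_rng(recipe.seed)
        values = values + rng.normal(0.0, recipe.noise_sigma, size=values.shape)
    return IntensityProfile(values=values, step=recipe.step)


# Anterior-posterior clustering: two hot spots flanking the swim bladder,
# emulating the bimodal axial distribution seen in larval fish.
AP_CLUSTER_CENTERS = (220.0, 450.0)
AP_CLUSTER_SD = 60.0
AP_EXTENT = 666.0


def make_cohort_tables(
    n_fish: int,
    count_mean: float = 90.0,
    count_dispersion: float = 12.68,
    per_cell_mean: float = 1000.0,
    per_cell_cv: float = 3.5,
    seed: int = 0,
    group: str | None = None,
    with_positions: bool = False,
) -> list[FishRecord]:
    """Draw a synthetic per-fish cohort of neutrophil counts and intensities.

    Counts are negative-binomial with the given mean and dispersion
    (shape parameter k; variance = mean + mean²/k).  The default
    (mean 90, k ≈ 12.7) gives SD/mean = 0.30, the inter-individual
    variability observed in 5-dpf larvae.  Per-fish total intensity is the
    sum of lognormal per-cell intensities; the default per-cell CV of 3.5
    makes total intensity only weakly correlated with count (R² ≈ 0.4 at
    these count statistics — see the methods note for the derivation).
    Optionally draws per-cell anterior-posterior positions from a
    two-cluster mixture flanking the swim bladder.
    """
    if n_fish < 1:
        raise ValidationError("n_fish must be >= 1")
    if count_dispersion <= 0:
        raise ValidationError("count dispersion must be positive")
    if count_mean <= 0:
        raise ValidationError("count mean must be positive")
    if per_cell_cv < 0:
        raise ValidationError("per-cell CV must be non-negative")
    rng = np.random.default_rng(seed)
    k = float(count_dispersion)
    p = k / (k + float(count_mean))
    counts = rng.negative_binomial(k, p, size=n_fish)
    if per_cell_cv > 0:
        # lognormal with mean per_cell_mean and CV per_cell_cv
        sigma2 = np.log(1.0 + per_cell_cv**2)
        mu = np.log(per_cell_mean) - sigma2 / 2.0
        sigma = np.sqrt(sigma2)
    records: list[FishRecord] = []
    for i, c in enumerate(counts):
        c = int(c)
        if per_cell_cv == 0:
            total = float(c) * per_cell_mean
        else:
            total = float(np.sum(rng.lognormal(mu, sigma, size=c))) if c > 0 else 0.0
        positions = None
        if with_positions and c > 0:
            which = rng.integers(0, len(AP_CLUSTER_CENTERS), size=c)
            pos = rng.normal(np.asarray(AP_CLUSTER_CENTERS)[which], AP_CLUSTER_SD)
            positions = list(np.clip(pos, 0.0, AP_EXTENT))
        records.append(
            FishRecord(
                fish_id=f"fish{i:03d}",
                count=c,
                total_intensity=total,
                group=group,
                ap_positions=positions,
            )
        )
    return records


# --------------------------------------------------------------------------
# Canned study conditions
# --------------------------------------------------------------------------

# Printed group statistics of the LPS-exposure experiment: mean ± sample SD
# neutrophil counts and group sizes.  Used as negative-binomial generator
# parameters for synthetic stand-in cohorts.
STUDY_GROUP_CONDITIONS: dict[str, dict[str, float]] = {
    "control_5dpf": {"mean": 85.0, "sd": 17.0, "n": 13},
    "lps_2h": {"mean": 87.6, "sd": 27.6, "n": 14},
    "control_6dpf": {"mean": 95.1, "sd": 23.4, "n": 21},
    "lps_24h": {"mean": 114.2, "sd": 38.1, "n": 19},
}


def dispersion_from_mean_sd(mean: float, sd: float) -> float:
    """Negative-binomial shape k from a target mean and SD (Var = m + m²/k).

    Distributions at or below Poisson variance get a very large k
    (effectively Poisson).
    """
    excess = sd**2 - mean
    if excess <= 0:
        return 1e6
    return mean**2 / excess


def make_study_group(name: str, seed: int = 0, **kwargs) -> list[FishRecord]:
    """Synthetic stand-in for one printed study group, at its printed
    mean/SD/size.  Not the original per-fish data."""
    cond = STUDY_GROUP_CONDITIONS[name]
    return make_cohort_tables(
        n_fish=int(cond["n"]),
        count_mean=cond["mean"],
        count_dispersion=dispersion_from_mean_sd(cond["mean"], cond["sd"]),
        seed=seed,
        group=name,
        **kwargs,
    )


def cohort_stack_recipe(
    n_blobs: int = 20,
    seed: int = 0,
    snr: float = 10.0,
    radius: float = 3.5,
    noise_model: str = "gaussian",
    noise_sd: float = 10.0,
    speckle_centers: tuple = (),
) -> StackRecipe:
    """A compact neutrophil-cohort stack at the instrument voxel spacing.

    Up to 27 neutrophil-sized cells (Gaussian radius 3.5 μm ≈ 8 μm FWHM) on
    a jittered 3×3×3 site grid; pairwise separation stays well above
    6·radius so every planted cell is recoverable as a distinct object.
    SNR is (blurred blob peak − background) / noise sd; the Gaussian noise
    model makes that planted SNR exact (with Poisson noise, the sd at the
    background level, √background, is used).
    """
    if n_blobs > 27:
        raise ValidationError("site grid supports at most 27 blobs")
    spacing = DEFAULT_SPACING
    shape = (48, 256, 256)  # extent (z, y, x) = (120.0, 83.2, 83.2) μm
    background = 100.0
    psf = DEFAULT_PSF_SIGMA
    sd = noise_sd if noise_model == "gaussian" else float(np.sqrt(background))
    factor = 1.0
    for r, s in zip((radius,) * 3, psf):
        factor *= r / float(np.hypot(r, s))
    peak = snr * sd / factor
    rng = np.random.default_rng(seed)
    sites = [(x, y, z) for z in (25.0, 60.0, 95.0) for y in (15.0, 41.6, 68.2) for x in (15.0, 41.6, 68.2)]
    rng.shuffle(sites)
    blobs = [
        BlobSpec(
            center=tuple(c + rng.uniform(-1.0, 1.0) for c in site),
            radii=(radius,) * 3,
            peak_intensity=peak,
        )
        for site in sites[:n_blobs]
    ]
    return StackRecipe(
        shape=shape,
        voxel_spacing=spacing,
        blobs=blobs,
        background_level=background,
        psf_sigma=psf,
        noise_model=noise_model,
        noise_param=noise_sd if noise_model == "gaussian" else 1.0,
        seed=seed,
        speckles=[(c, 3, 10.0 * background) for c in speckle_centers],
    )


def occlusion_stack_recipe(n_pairs: int = 3, n_singles: int = 3, seed: int = 0, snr: float = 10.0) -> StackRecipe:
    """A stack where ``n_pairs`` (x, y) sites each hold two cells at
    different depths: a maximum-intensity projection merges each pair, so
    the 2D count undershoots the 3D count by exactly ``n_pairs`` cells."""
    if n_pairs + n_singles > 9:
        raise ValidationError("at most 9 (x, y) sites available")
    base = cohort_stack_recipe(n_blobs=0, seed=seed, snr=snr)
    rng = np.random.default_rng(seed)
    radius, psf = 3.5, DEFAULT_PSF_SIGMA
    factor = 1.0
    for s in psf:
        factor *= radius / float(np.hypot(radius, s))
    peak = snr * 10.0 / factor
    xy_sites = [(x, y) for y in (15.0, 41.6, 68.2) for x in (15.0, 41.6, 68.2)]
    rng.shuffle(xy_sites)
    blobs = []
    for i, (x, y) in enumerate(xy_sites[: n_pairs + n_singles]):
        zs = (25.0, 95.0) if i < n_pairs else (60.0,)
        for z in zs:
            center = (x + rng.uniform(-1, 1), y + rng.uniform(-1, 1), z + rng.uniform(-1, 1))
            blobs.append(BlobSpec(center, (radius,) * 3, peak))
    base.blobs = blobs
    return base


def recipe_to_dict(recipe) -> dict:
    """Flatten a recipe dataclass for config-file serialization."""
    d = asdict(recipe)
    if "blobs" in d:
        d["blobs"] = [asdict(b) if not isinstance(b, dict) else b for b in d["blobs"]]
    return d
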