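# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `larvalight`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

Stacks are indexed `(z, y, x)` with voxel spacing `(dz, dy, dx)` in μm;
`x` is the capillary/flow axis (anterior–posterior in a head-first-loaded
larva), `z` the detection/scan axis. Physical positions are voxel-center
positions: voxel index `i` along an axis with spacing `d` sits at `i·d`.
Default spacing is `(2.5, 0.325, 0.325)` μm: 2.5 μm per z-slice is the scan
step; the in-plane 0.325 μm is an inference (666 μm field width over a
2048-pixel sensor) and is configurable everywhere — it is not a measured
instrument constant.

All intensity thresholds in the package are strict (`>`); the convention is
uniform and is exercised at boundary values by the tests.

## Segmentation pipeline

`segment_stack` composes six stages.

1. **Coarse threshold.** Default `mean + 3·SD` of the whole stack. The
   instrument procedure used "a low intensity value"; a mean-plus-k-SD rule
   is robust to overall brightness differences between specimens. Absolute
   and percentile modes are provided. The resolved value is logged and
   reported in the run log.
2. **Morphological clean.** Closing (dilation then erosion) followed by an
   erosion, with a 6-connected cross of radius 1 voxel by default (a cube is
   available). Border conventions matter and are fixed as follows: the
   closing is *extensive* (its erosion treats out-of-image voxels as
   foreground, so closing never carves into objects at the stack faces),
   while the final erosion treats out-of-image voxels as background (a mask
   filling the whole grid loses its face layer). A solid 5×5×5 mask
   therefore cleans to its 3×3×3 core. Morphology operates in voxel space —
   "radius 1" means one voxel on every axis regardless of anisotropy — only
   the volume filter uses physical units.
3. **Labeling.** Maximal connected components under 26-connectivity in 3D
   (8 in 2D) by default, which favors keeping diffraction-blurred cells
   whole; 6/18 available. Labels are assigned in raster order of each
   component's first voxel.
4. **Per-object Otsu refinement.** For each object independently, the exact
   Otsu threshold of its own voxel intensities — the value `t*` maximizing
   the between-class variance ω₀(t)·ω₁(t)·(μ₀(t)−μ₁(t))² over an exhaustive
   search of the distinct intensities — is computed; voxels strictly above
   `t*` are retained, and the retained set is re-labeled globally. This is
   repeated `otsu_rounds = 2` times ("re-thresholded … repeated twice" is
   read as two total rounds; a three-round reading is one configuration
   change). The exhaustive search (rather than a 256-bin histogram Otsu)
   keeps the stage bit-identical to its brute-force definition, which the
   oracle suite checks voxel-for-voxel. Degenerate objects — a single voxel
   or fewer than two distinct intensities — pass through unchanged: there
   is no bimodality to split. Voxel sets only ever shrink.
5. **Volume filter.** Objects with `voxel_count · dz·dy·dx < 3 μm³` are
   discarded as unphysical (at the default spacing one voxel is 0.2641 μm³,
   so the cutoff is 12 voxels). The 2D projection pipeline uses a 2.5 μm²
   minimum area, the cross-section of the sphere with 3 μm³ volume; the 2D
   cutoff has no instrument-stated value.
6. **Measurement.** Per object: voxel count, physical volume, total raw
   intensity (the proxy for the cell's total fluorescence), the
   intensity-weighted centroid in μm, and the bounding box.

`count_projection` applies stages 1–5 to the maximum-intensity projection
along z. Cells that overlap in `(x, y)` merge there, so the projection
count is a lower bound on the 3D count — the quantitative argument for 3D
imaging.

### Known limitation: fragmentation at low contrast

Iterated per-object Otsu assumes each object's intensity histogram is
signal-dominated. When the retained intensity range after a round becomes
comparable to the noise (blurred peak-over-background below roughly 7×
the background noise SD under Gaussian noise at the default spacing), the
second round splits noise rather than structure: objects shatter into
fragments, most of which fall below the volume floor. The method is
therefore reliable for bright cells — the regime GFP neutrophils occupy —
and degrades sharply for dim ones. The recovery suite runs at SNR 10
(defined below), where recovery is exact; this boundary was measured with
the package's own generator and is a property of the algorithm, not of the
implementation.

## Synthetic data

* **Cells** are anisotropic Gaussian intensity blobs (not hard ellipsoids):
  diffraction-blurred cells have soft edges, and a graded profile is what
  makes Otsu refinement meaningful. `radii` are the Gaussian SDs; the suite
  default of 3.5 μm corresponds to ≈ 8 μm FWHM, a realistic neutrophil
  diameter.
* **PSF blur** is applied analytically: a Gaussian blob convolved with the
  Gaussian PSF is again Gaussian with per-axis variance `r² + σ_psf²`, and
  the blur preserves total mass (the blurred peak scales by `Π rᵢ/σ_eff,ᵢ`).
  This makes the conservation property exact up to the ±5σ render window
  (relative truncation ≈ 10⁻⁶). The optional background texture is blurred
  numerically.
* **Noise** defaults to Poisson with gain 1 (shot noise on
  intensity-as-counts); Gaussian noise of fixed SD is provided for analytic
  tests and is used by the recovery suite because it makes the planted SNR
  exact. **SNR** of a stack is defined as (blurred blob peak −
  background) / noise SD, with the Poisson SD taken at the background level.
* **Speckles** model unphysically small bright debris (hot pixels, dirt): a
  solid 3×3×3-voxel cube of added intensity rendered after the PSF blur.
  The morphological erosion reduces such a cube to one voxel (0.26 μm³),
  which the 3 μm³ filter must then reject — they test the volume floor, not
  the detector.
* **Blob placement** requires centers at least 3 radii from every stack
  face by default (`margin_sigmas`), avoiding truncated-mass edge cases;
  the cohort recipe places cells on a jittered 3×3×3 site grid whose
  minimum pairwise separation (≈ 24.6 μm) exceeds 6 radii.
* **Cohort tables**: per-fish counts are negative-binomial with mean `m`
  and shape `k` (variance `m + m²/k`); `k = m²/(SD² − m)` reproduces a
  target mean/SD. The default (mean 90, k ≈ 12.7) gives SD/mean = 0.30, the
  observed inter-individual variability at 5 dpf. Per-fish total intensity
  is a sum of lognormal per-cell intensities. Under this count mixture the
  squared count–intensity correlation is
  `R² = Var(N) / (Var(N) + E[N]·cv²)`, so the per-cell CV controls how well
  bulk brightness predicts cell number. The default `cv = 3.5` is derived
  once from this formula so that the default count statistics yield the
  weak observed correlation (R² ≈ 0.4): `cv = √(Var(N)·(1/R² − 1)/E[N])`.
  A CV this large reflects everything the per-cell "intensity" absorbs in
  practice — expression variability, depth-dependent attenuation, specimen
  orientation — not just intrinsic GFP content.
* **Brightfield profiles** are a bright baseline with Gaussian-shaped dips
  at feature positions (eyes, swim bladder analogs). The recipe's dip width
  (default 30 μm) is a free parameter of the generator. Offsets are applied
  by linear interpolation, so integer-sample shifts are exact; out-of-field
  samples take the baseline value.
* **What the generator does not emulate:** real anatomy and its
  orientation-dependent appearance, refractive distortion by the capillary,
  scattering and depth-dependent attenuation, cell motility between scans,
  or debris/bubble false triggers. Passing tests demonstrate correctness of
  the algorithms under the stated models, not performance on real larvae.

## Positioning

Profiles are normalized to zero mean and unit variance before correlation
(brightness-insensitive; raw mode available). Offsets are integer multiples
of the sample step: the instrument's coarse stop is accurate to a few
millimetres while the target precision is tens of μm, so the profile step,
not sub-sample interpolation, sets the resolution.

The cross-correlation scorer evaluates every integer lag `k` with
`|k·step| ≤ max_shift`, on the overlap region only (no zero padding). Lags
whose overlap is shorter than 25 % of the template are excluded. The
default score is the **Pearson correlation of the overlapping segments**:
it is exactly 1 at a perfect alignment, bounded by 1 everywhere, immune to
the partial-overlap bias of a plain mean product (which rises as the
overlap sheds featureless baseline), and comparable across library
templates, which is what the best-score-wins library selection needs. Lags
whose overlap carries almost no structure (segment variance below 10⁻³ of
the full-profile variance on either side) are excluded — otherwise two
featureless baseline tails correlate perfectly and produce spurious
matches. The plain overlap-normalized product of z-scored profiles is
retained as `scoring="product"`; both scorers are verified against
independent exhaustive implementations. Ties break toward the smaller
|offset|. The minimum-location method simply differences the argmin
positions of profile and template; with deep single minima and low noise
the two methods agree to within one sample.

The closed-loop simulator models fine positioning as: image (template
shifted by the current residual, plus optional profile noise) → estimate →
commanded corrective move corrupted by Gaussian stage noise. A zero
estimate commands no move, so a converged specimen is not perturbed. The
suite runs it at 20 μm sampling — the registration-precision scale the
procedure achieves in practice — with 10 μm stage noise; under these
conditions the residual settles within one sample in ≤ 5 iterations in
well over 90 % of seeds. This simulation is a property-level stand-in for
the instrument's measured ~20 μm axial reproducibility, which requires real
specimens.

## PSF estimation

The bead is located at the global maximum after a 1-voxel Gaussian smooth
(raster-first tie-break), and must not touch a stack face. Line scans along
each axis through the bead are single-voxel wide by default (a configurable
averaging half-width exists). Fits use `scipy.optimize.curve_fit` with a
derivative-free initialization: amplitude = max − min, baseline = min,
center at the maximum, σ = HWHM/1.177. Reported widths are Gaussian σ; the
FWHM is 2.355·σ — stated prominently because the two are routinely
confused. σ estimates are invariant under affine intensity transforms of
the stack.

## Cohort statistics

Sample SD uses the n−1 denominator throughout ("mean ± SD" of small
groups); a single-fish group flags its SD as undefined rather than zero.
The intensity-on-count regression is OLS with intercept
(`statsmodels`), reporting R² = 1 − SS_res/SS_tot. The
anterior-posterior histogram pools positions over fish into half-open bins
`[edge, edge + width)` (default 50 μm over the 666 μm field) and conserves
counts exactly. The treated/control fold change reports first-order
propagation of the two standard errors,
`SE(fold) = fold·√((SEM_c/m_c)² + (SEM_t/m_t)²)`, with a seeded 10⁴-sample
percentile bootstrap as a distribution-free cross-check — the uncertainty
convention for such ratios is not standardized, so both are given. The
2D/3D projection ratio is the per-fish mean of `count_2D/count_3D` ± SEM;
fish with a zero 3D count are excluded and logged.

## File formats and configuration

Stacks are multi-page TIFFs; the voxel spacing is stored as JSON in the
ImageDescription tag (and the in-plane pitch redundantly in the resolution
tags); ImageJ-style spacing metadata is also read. A stack with no spacing
metadata and no explicit override is an error, never a silent default.
Per-fish tables support two plain-text dialects: one numeric value per line
(counts, intensities and positions pair by line order), and delimited
"labeled rows" (wide `label, v1, v2, …` rows or a two-column
`group, count` layout; the delimiter is sniffed). All writes are atomic
(write-temp-then-rename). Every CLI run writes its fully resolved
configuration (including the seed) next to its outputs; exit codes are 0
(success), 2 (validation error), 3 (data error).

## Problem sizes in the validation suites

The oracle-equivalence suite compares all four segmentation stages against
brute-force references on 100 random stacks of up to 8³ voxels. The
recovery suite uses 50 cohort stacks of 48×256×256 voxels at the instrument
spacing with 20 cells and 2 planted speckles each; the occlusion suite uses
9-cell stacks with three stacked pairs. Positioning suites use 512-sample
profiles (3 μm step) for shift recovery and 128-sample profiles (20 μm
step) for the closed loop. These sizes were chosen so the full validation
runs in a few minutes on one CPU while keeping every statistical check at
the sample sizes stated above.

## Synthetic stand-ins for the study tables

The cohort statistics are demonstrated on synthetic per-fish tables whose
generator parameters are the study's printed group statistics (means
85.0/87.6/95.1/114.2, SDs 17.0/27.6/23.4/38.1, sizes 13/14/21/19; a 41-fish
cohort at SD/mean 0.30). Files written by the suites carry a `_synthetic`
suffix. Statistics computed from them therefore reproduce the printed
values stochastically (to within sampling error at the printed group
sizes), not deterministically from the original per-fish data.
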