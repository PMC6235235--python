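# larvalight

Analysis toolkit for automated, high-throughput light-sheet fluorescence
microscopy (LSFM) of larval zebrafish. It implements the computational side
of a fluidic LSFM workflow in which anaesthetized larvae flow through a
glass capillary, are stopped and fine-positioned in front of the imaging
objective using brightfield images, and are scanned in 3D to count and
measure GFP-expressing neutrophils:

* **Specimen positioning** — brightfield frames are averaged along the
  short axis into a 1D intensity profile whose strong minima (eyes, swim
  bladder) are registered against a stored template library, either by
  cross-correlation or by comparing minimum locations; a closed-loop
  simulator models iterated stage corrections.
* **Optical characterization** — the point spread function is estimated
  from stacks of sub-resolution fluorescent beads by least-squares Gaussian
  fits `A·exp(−(u−u₀)²/2σ²) + B` to axial line scans; the reported width is
  the Gaussian **σ** (not FWHM).
* **Neutrophil segmentation** — 3D stacks are thresholded at a low
  intensity value, cleaned by morphological closing and erosion (radius
  1 voxel), labeled into connected components, re-thresholded per object
  with an exact Otsu filter (maximizing the between-class variance
  ω₀ω₁(μ₀−μ₁)²) and re-labeled — repeated twice — and objects below
  3 μm³ are discarded as unphysical. A 2D variant runs on the
  maximum-intensity projection to mimic widefield counting.
* **Cohort statistics** — per-fish group summaries (mean ± sample SD,
  SD/mean), OLS regression of total fluorescence intensity on cell count
  (R²), pooled anterior-posterior histograms, control-vs-treated fold
  change with propagated and bootstrap uncertainty, and 2D/3D count ratios.
* **Synthetic data** — seed-deterministic generators for
  ground-truth-annotated cell stacks (anisotropic Gaussian blobs, analytic
  PSF blur, Poisson/Gaussian noise, planted sub-cellular speckles), bead
  stacks, brightfield profiles, and negative-binomial per-fish cohort
  tables, so the entire pipeline is testable without instrument data.

Who it is for: microscopists building or validating fluidic light-sheet
instruments, and image analysts who need a reference implementation of
iterated per-object Otsu segmentation with physically meaningful defaults
(voxel spacing (dz, dy, dx) = (2.5, 0.325, 0.325) μm, PSF σ = (0.6, 0.6,
3.4) μm).

## Worked example

Generate a synthetic cohort stack (20 planted cells at the instrument voxel
spacing), segment it, and compare 3D and projection counts:

```bash
$ larvalight pipeline --out demo --seed 7
{"planted_blobs": 20, "detected_3d": 20, "detected_2d_projection": 7,
 "stage_counts": {"above_threshold_voxels": 47831,
                  "after_morphology_voxels": 22266,
                  "labeled_objects": 61,
                  "after_otsu_objects": 299,
                  "after_volume_filter_objects": 20},
 "seed": 7}
```

All 20 planted neutrophils are recovered in 3D (`detected_3d`). The stage
log shows the pipeline at work: 61 coarse candidate objects (cells plus
noise clumps) briefly fragment during per-object Otsu refinement (299) and
the 3 μm³ volume filter leaves exactly the 20 real cells. The projection
count (7) is far lower because the demo stack intentionally stacks cells at
shared (x, y) sites: cells behind one another merge in a maximum-intensity
projection, which is why 3D imaging is needed for accurate counts.

Estimate the PSF from a noise-free synthetic bead stack:

```bash
$ larvalight simulate --kind bead --out beads --seed 0 --snr 0
$ larvalight psf --stack beads/beads.tif
{"sigma_x_um": 0.6, "sigma_y_um": 0.6, "sigma_z_um": 3.4, ...}
```

The round trip recovers the generating widths: σxy = 0.6 μm in the sheet
plane and σz = 3.4 μm along the detection axis (the sheet thickness).

The same operations are available as a library:

```python
from larvalight import make_neutrophil_stack, segment_stack
from larvalight.synthetic import cohort_stack_recipe

grid, truth = make_neutrophil_stack(cohort_stack_recipe(n_blobs=20, seed=7))
result = segment_stack(grid)
print(len(result), "objects;", result.stage_counts)
```

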