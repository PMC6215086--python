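# serialoct

Reconstruction and analysis toolkit for dual-resolution serial blockface
optical coherence tomography (OCT) of ex vivo brain tissue, with a
built-in synthetic phantom bench so the whole chain runs without an
instrument.

Serial blockface OCT images the cut face of an embedded sample tile by
tile, slices off the imaged layer with a vibratome, and repeats through
the whole specimen; a second, high-magnification arm acquires
dynamic-focus volumes (OCM) in selected regions of interest.  This
package implements the computation that turns such an acquisition into
science:

* **Fringe reconstruction** — reference subtraction, Gaussian spectral
  apodization (mu = 1310 nm, sigma = 20 nm), inverse FFT, Hermitian
  half-range; calibrated so a reflector of amplitude *a* reconstructs to
  intensity *a²*.
* **Attenuation** — per-A-line fits of the single-scattering model with
  the confocal axial envelope, `I(z) = i0 T(z) exp(-2 mu (z - z_s))`, and
  depth compensation (per-A-line, tile-median, pooled, or depth-resolved).
* **Mosaicking** — affine stage model `p = A pM + b` calibrated by phase
  correlation, distance-transform (diffusion steady-state) blending that
  is an exact partition of unity, 2-D stitching on recorded positions, and
  3-D assembly at 25 um isotropic with ~100 um feathered slice overlaps.
* **Autofocus & field curvature** — Fibonacci-search focus optimization
  (final bracket `(b-a)/F(n+1)`), derivative-of-Gaussian water/tissue
  interface detection, and Zernike decomposition (j <= 5) of the
  interface surface.
* **Automated ROI selection** — bilateral + Otsu tissue segmentation, a
  probability map biased toward bright/high-contrast tissue (75 um
  smoothing), and seeded sampling under a 250 um boundary margin and a
  pairwise separation constraint, scheduled every fourth slice.
* **dMRI support** — the 70-volume multishell scheme (6/15/42 directions
  at b = 400/1066/2000 s/mm² + 7 interlaced b0, 125 um voxels),
  CSF-anchored temporal drift compensation (sigma = 1 subscan smoothing),
  and the data-driven NuFO threshold (1.5x ventricle AFD_max).
* **Multimodal comparison** — per-ROI OCM features (⟨rN⟩, sigma_r, ⟨mu⟩,
  sigma_mu), quartile grouping by each dMRI metric, and Welch t-tests for
  all 4 x 5 = 20 feature/metric pairs at the Bonferroni-corrected
  threshold 0.05/20 = 0.0025.
* **Phantom** — a seeded digital tissue block (cortical laminae, crossing
  fiber bundles, vessels, a ventricle, a toy atlas) plus simulators for
  fringes, focal stacks, drifting DWI series and metric maps; everything
  downstream is validated against it.

## Worked example

Simulate a brain block, run the full serial acquisition, and reassemble it:

```python
import numpy as np
from serialoct import phantom, pipeline

ph = phantom.make_phantom(seed=7)           # 1.2 x 1.2 x 0.8 mm block
res = pipeline.reconstruct_phantom_brain(ph, seed=1, compensation="pooled")
print("pooled attenuation: %.2f mm^-1" % res.pooled_mu_mm)
print("assembled volume:", res.brain.intensity.shape, "@ 25 um")

oracle = pipeline.assemble_ground_truth(ph)
ref, tissue = pipeline.phantom_reference(ph, 25.0)
a = pipeline.brain_to_reference_grid(res.brain, ref.shape, 25.0)
g = pipeline.brain_to_reference_grid(oracle, ref.shape, 25.0)
print("round-trip correlation: %.4f" % np.corrcoef(a[tissue], g[tissue])[0, 1])
```

prints

```
pooled attenuation: 1.40 mm^-1
assembled volume: (52, 52, 36) @ 25 um
round-trip correlation: 0.9985
```

The pooled coefficient sits in the gray-matter range of the phantom
(1.5 mm^-1 ground truth), the 1.3 mm mosaic at 25 um gives the 52-voxel
lateral extent, and the correlation against the ground-truth assembly of
the same acquisition shows the fringe synthesis, reconstruction,
stitching and slice assembly are mutually consistent to ~0.1%.

Automatic ROI selection on a slice image:

```python
from serialoct import roiselect
aip = ph.reflectivity.mean(axis=2)
mask = roiselect.segment_tissue(aip, pixel_um=ph.voxel_size_um)
pmap = roiselect.probability_map(aip, mask)                # sums to 1 on tissue
rois = roiselect.sample_rois(pmap, mask, n=10, margin_um=250.0,
                             min_separation_um=100.0, seed=5)
print(len(rois), "ROIs, first at", rois[0].center_um, "um")
```

A command-line surface wraps the main workflows:
`serialoct stitch`, `serialoct roi-select`, `serialoct drift`,
`serialoct compare` (see `serialoct --help`).

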