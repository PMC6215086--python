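# Methods

`serialoct` re-creates, in software, the computational chain of a
dual-resolution serial blockface OCT microscope: swept-source fringe
reconstruction, attenuation compensation, tile mosaicking, whole-block
assembly, autofocus and interface detection, automated ROI selection,
multiresolution ROI bookkeeping, diffusion-MRI drift compensation, and the
statistical comparison of OCT image features with diffusion metrics.  A
seeded digital phantom replaces the instrument, so every stage runs and is
validated at desk scale.

## Coordinate and depth conventions

x, y are the stage-plane axes, z is depth into the sample; all lengths are
micrometres internally.  Fringes are sampled linearly in wavenumber over
the source bandwidth (1310 nm centre, 100 nm tuning range, 512 samples by
default).  One reconstructed axial bin corresponds to an optical path of
`2*pi/(N*dk)`; physical depth divides this by 2 (double pass) and by 1.33
(water/tissue refractive index), giving 6.43 um per bin on the default
grid.  Pixel centres sit at half-integer physical coordinates; extents are
half-open; intensity resampling is linear, label resampling is
nearest-neighbour.

## Fringe model and A-line reconstruction

The simulator inverts the reconstruction: for each A-line it computes the
single-scattering ground-truth intensity
`I(z) = R(z) * T(z) * exp(-2 \int mu dz')`, with the confocal axial
envelope `T(z) = [((z - z_f)/z_r)^2 + 1]^{-1}` (apparent Rayleigh range
`z_r = 150 um` by default), and synthesizes the fringe as a sum of
cosines with amplitude `sqrt(I)` at the exact DFT bin frequencies.  Two
phase conventions matter:

* **Zero spectral phase at band centre.**  Each reflector's cosine is
  referenced to the apodization centre wavelength.  Because the Gaussian
  spectral window is centred mid-band, its transfer kernel carries a phase
  ramp of roughly pi per bin when phases are referenced to the grid origin;
  neighbouring depth bins then cancel coherently and a smooth profile loses
  most of its amplitude.  Band-centre referencing (the transform-limited
  convention) makes the blur kernel all-positive, so the magnitude of the
  reconstruction is a gentle blur of `sqrt(I)` — the "controllable
  magnitude" regime the simulator is built for.  An optional speckle switch
  randomizes per-depth phases instead.
* **One global carrier phase per A-line** (uniform, seeded).  The FFT
  magnitude of a single A-line is unchanged, but laterally the signals
  decorrelate, so the tile-average fringe converges to the common
  source-envelope background — which is what makes mean-fringe reference
  subtraction work on the instrument.

Reconstruction is the standard chain: subtract the reference fringe
(tile average; optionally low-passed along k so that the slowly varying
background estimate does not re-inject the residual average *signal*),
multiply by the peak-normalized Gaussian apodization window
(mu = 1310 nm, sigma = 20 nm, evaluated in wavelength and resampled to the
k-grid), FFT, keep the first half of the axial range (Hermitian symmetry),
and square the calibrated magnitude (`2|F|/sum(w)`), so an on-bin reflector
of amplitude `a` reconstructs to intensity `a^2`.

Measured on a simulated mirror, the axial point-spread FWHM on this grid
is ~12 um in tissue (~16 um in air).  The nominal figure usually quoted
for this class of system (7.5 um) corresponds to the full 100 nm bandwidth
rather than a sigma = 20 nm Gaussian window; the suite asserts only the
measured value's order of magnitude, and no result depends on the nominal
number.

## Attenuation estimation and compensation

Per A-line the model `I(z) = i0 * T(z) * exp(-2 mu (z - z_surf))` is
fitted by weighted least squares on log-intensity.  Two weightings are
provided, each the generalized-least-squares choice for one error regime:
`intensity` (weights `I^2`) when additive detector noise dominates — this
is the configuration used for coefficient recovery on clean decay profiles
(noiseless recovery is exact; at 1% noise the bias stays below ~4%) — and
`uniform` when multiplicative tissue texture dominates (constant
log-variance), used by the whole-block pipeline.

For tiles that enter the tissue through water or agarose, the fit locates
each A-line's own tissue onset: the first bin whose intensity reaches 20%
of the A-line peak (agarose backscatter sits near 10% of a tissue peak
after reconstruction), skipping 20 um to clear the axial edge-response
ramp; only the first contiguous above-floor segment is fitted, with the
same trim before the tissue exit, so edge ramps at the brain boundary or
block bottom never enter the slope.  A-lines whose peak stays below 2% of
the tile maximum carry no tissue and are flagged invalid.

Compensation divides by `T(z)` and the fitted decay from each A-line's
onset.  Three policies exist: per-A-line coefficients, the tile median,
and a brain-level pooled median over all valid A-lines of all tiles.  The
pipeline default is the pooled coefficient: on the phantom, individual
slopes alias residual lamination and bundle crossings into noisy
coefficients, and tiles imaging little tissue (thin last slice, agarose
corners) cannot support their own estimate.  A backscatter-proportional
depth-resolved variant (`compensate_depth_resolved`) is provided for
tissues where attenuation tracks backscatter; on this phantom, whose
vessels and ventricle violate that proportionality, it is not the default.
A single pooled coefficient cannot restore the shadows cast by strongly
attenuating bundles (mu = 5 vs 1.5 mm^-1, 75-100 um thick: shadow factor
~0.5); this is the known limitation of single-scattering compensation and
the reason the reflectivity-recovery correlation of the full inversion
(~0.91) is reported separately from the geometric reassembly round trip
(~0.998).

## Mosaicking and assembly

Tiles are placed by recorded stage positions mapped through the affine
stage model `p = A pM + b`, calibrated by least squares from commanded
microstep displacements and phase-correlation-measured shifts; no pairwise
registration is performed.  Blending weights are each tile's Euclidean
distance to its own boundary, normalized across covering tiles — the
steady state of the diffusion feathering construction — giving an exact
partition of unity on covered pixels.  Slices are assembled on a 25 um
isotropic grid; each slice contributes from its cut face down to 1.5x the
slice spacing (200 um slices, ~100 um imaging overlap into the next cut),
blended with 1-D distance feathering in z.  The slice AIP averages the
first 800 um below the surface by default (the depth range that carries
usable tissue contrast at the survey resolution); the phantom pipeline
uses 300 um because its slices are only imaged that deep.

## Autofocus, interface, field curvature

The autofocus metric is the mean intensity of the central A-line,
maximized by classical Fibonacci elimination: after `n` evaluations the
bracket is `(b-a)/F(n+1)` (the degenerate final comparison is resolved
with a 1e-9 relative offset).  Linear intensity is used; the choice only
rescales the metric, not the argmax.  The water/tissue interface is the
depth of the maximum rising (dark-to-bright) response to a first-derivative-
of-Gaussian filter, normalized so a clean step scores 1 (threshold 0.3;
sigma defaults to one 50 um scan step).  Focal-plane curvature is
characterized by least-squares projection of the interface map onto ANSI
single-index Zernike polynomials j = 0..5 (piston, tip, tilt, oblique
astigmatism, defocus, vertical astigmatism), orthonormal on the unit disk;
the disk mapping (centre, radius) can be pinned explicitly because
non-piston coefficients depend on it.

Dynamic-focus (OCM) stacks advance the focal plane in 16 um steps and are
fused by depth-dependent Gaussian weighting centred on each member's focal
plane.  The weight half-width at half-maximum equals half the plane
spacing, so the in-focus member dominates (>0.9) at its own plane and the
weights are a partition of unity at every depth.  The published
Gabor-domain fusion needs modelled defocus kernels that are not available
here; the Gaussian weighting is a deliberate simplification.

## Automated ROI selection

Tissue is segmented from the slice AIP by bilateral denoising (spatial
sigma 3 px, range sigma 10% of the dynamic range), Otsu thresholding
(tissue = bright class), median filtering and morphological hole filling.
The selection-bias map is the sum of the min-max normalized AIP and the
normalized deviation from the mean tissue intensity, Gaussian-smoothed
with sigma = 75 um (smoothing before masking), zeroed outside the mask and
normalized to unit mass; it is invariant to affine intensity rescaling,
and a constant AIP degenerates to the uniform distribution.  ROI centres
are drawn without replacement from this map, restricted to candidates at
least 250 um from the tissue boundary (Euclidean distance transform) and
rejected when closer than the centre-to-centre separation limit to an
accepted ROI; sampling is capped at 100 attempts per requested ROI and is
bit-reproducible given the seed.  Selection runs every fourth slice by
default.

## Multiresolution bookkeeping

High-resolution ROIs are relocated in the survey image by zero-mean
normalized cross-correlation over a search window (+-1 mm by default,
matching typical commanded-vs-actual offsets), rasterized as axis-aligned
blocks into a label volume on the assembled-brain grid (last writer wins
on collision, logged), and carried through externally supplied 4x4 affine
transforms by nearest-neighbour pull-back — label transport never invents
values, and registration *estimation* is intentionally out of scope.
Per-ROI atlas structure fractions (with a fiber-tract flag) and NaN-aware
per-ROI metric means close the loop to the diffusion data.

## Diffusion scheme, drift, NuFO

The multishell scheme is 6/15/42 directions at b = 400/1066/2000 s/mm^2
plus 7 b = 0 volumes interlaced evenly — 70 volumes, 125 um isotropic
voxels for a 16x12x8 mm FOV on a 128x96x64 matrix.  Shell directions use
a seeded-rotation Fibonacci sphere: deterministic, quasi-uniform, and
sufficient because no result depends on electrostatic-repulsion
optimality.  Ventricles are segmented as the brightest 1% of in-brain b0
intensity.

Drift compensation exploits CSF isotropy: the mean signal over 1000
randomly chosen ventricle voxels per volume, minus a synthetic profile
constant within each shell, is the additive drift, smoothed temporally
with sigma = 1 subscan and subtracted from every voxel.  Two numerical
choices matter.  First, smoothing is applied within each shell's own
subseries: the generator injects drift multiplicatively
(`S = S0 exp(-b D)(1 + drift)`), so the additive drift profile is scaled
by the shell signal level, and a filter crossing shell-block or b0
boundaries would smear the large b0 excursions onto neighbouring high-b
volumes instead of suppressing noise.  Second, the Gaussian uses
linear-extrapolated padding, which keeps it unbiased at the endpoints of a
trending series — the exact regime (slow thermal ramps) the compensation
targets.  With both, a 1%-of-S0 linear ramp over the 70-volume series is
recovered with rms error well below 0.2% of S0, and post-correction
per-shell CSF means are flat at the drift-free noise level.  The
per-shell mean component of the drift is not identifiable (it is absorbed
by the synthetic profile); recovery is assessed against the per-shell-
centred truth.  A multiplicative correction variant exists behind a flag.

NuFO applies the data-driven rule: threshold = 1.5x the mean ventricle
AFD_max; a voxel's NuFO is the number of fODF peak amplitudes at or above
it.  Tensor/fODF/NODDI fitting itself is not reimplemented; metric maps
come from the phantom generator or from user files, and the ex vivo NODDI
settings used with such maps (d_iso = 1.0e-3 mm^2/s, d_par = 0.6e-3,
lambda1 = 0.5, lambda2 = 1.0e-3, dot compartment on) are recorded as
configuration metadata only.

## OCM/dMRI comparison

Per ROI: mean and standard deviation of reflectivity (normalized by an
external reference — by default the 99.9th percentile of all ROI AIP
intensities — and clipped to [0,1]) and of the fitted attenuation
coefficient.  ROIs are split at the 25/50/75% sample quantiles
(linear-interpolation definition; assignment by half-open intervals, so
grouping is invariant under monotone transforms) of each dMRI metric, and
each of the 4 features x 5 metrics = 20 pairs is tested Q1 vs Q4 with
Welch's unequal-variance t-test (a pooled-variance flag exists; the
unequal-variance form is the safer default when group spreads differ) at
the Bonferroni-corrected threshold alpha/20 = 0.0025.

## The phantom as a study condition

The digital block is a 1.2 x 1.2 x 0.8 mm ellipsoidal "brain" in an
agarose shell at 12.5 um voxels: thin cortical laminae (60 um radial
period, +-0.06 reflectivity about 0.30 — lamination thicker than the
attenuation-fit window would masquerade as attenuation and is also not
the anatomical scale), two crossing fiber ribbons (reflectivity 0.75,
mu = 5 mm^-1), dark vessels (mu = 3), one CSF ventricle (mu = 0.3), gray
matter at mu = 1.5, agarose at mu = 0.1 — plausible ex vivo values at
1310 nm.  The toy atlas has 6 labels, two flagged as fiber tracts.  The
acquisition geometry matches the instrument: 0.5 mm tiles at 20% overlap
(stride 0.4 mm), ~200 um slices with ~100 um imaging overlap, a 100 um
water standoff above the cut face, focus at the face.  The DWI simulator
reuses the phantom masks as a whole-brain-scale object with 125 um voxels,
S0 = 100 (tissue) / 300 (CSF), ex vivo diffusivities (CSF 1.0e-3 mm^2/s,
gray 0.35e-3, bundles 0.9e-3 / 0.15e-3 mm^2/s parallel/perpendicular) and
a default drift of 1% of S0, linear over the series.

What the phantom does **not** emulate: speckle statistics (off by
default), dispersion and sensitivity roll-off, illumination or shading
inhomogeneity, deformable slice distortion, MR relaxation/eddy/Rician
effects, and realistic fODF shapes.  Passing tests therefore demonstrate
the correctness of the geometry, the transforms, the estimators and the
statistics under the stated forward models — not robustness to every
artifact of real acquisitions.

Problem sizes in the validation suite (96x96x64 phantom, 3x3 tiles x 4
slices, 70-volume DWI series, 10^5 ROI draws, 2000 comparison-stage
simulations) were chosen so the full suite and the acceptance script each
complete in minutes on a single core while keeping every statistical check
well-powered.

## Known limitations

* Single-coefficient attenuation compensation cannot restore bundle
  shadows; the depth-resolved variant assumes attenuation proportional to
  backscatter, which dark vessels and CSF violate.
* The Fibonacci bracket is exact only up to the 1e-9 tie-breaking offset.
* Interface detection quantizes to the axial sampling step and assumes a
  rising (water-dark to tissue-bright) edge; polarity is configurable.
* ROI sampling is sequential rejection, so with aggressive separation
  constraints the achieved set can depend on draw order (as on the
  instrument) and may contain fewer ROIs than requested.
* `segment_ventricles` is a pure intensity quantile; on data whose CSF is
  not the brightest b0 compartment it needs an explicit mask.
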