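# Methods

This note documents the models, parameter choices and numerical decisions
behind `lcnquant`, in the spirit of a methods section: what is computed,
under which assumptions, and what the synthetic validation does and does
not demonstrate.

## The measurement problem

The lacuno-canalicular network (LCN) is the porosity left in bone matrix by
osteocytes: ellipsoidal lacunae (~10³ µm³ scale cavities) joined by
canaliculi of roughly 200–300 nm diameter. In label-free THG microscopy the
canaliculi appear bright against a mineralized-matrix background that is
itself structured and fluctuating, and the optical resolution
(~0.43 µm lateral, ~1.8 µm axial at 1.18 µm excitation) is above the
canalicular diameter. Network quantification therefore proceeds via
centerline statistics, not via direct volumetric segmentation: the skeleton
length yields the canalicular volume fraction under an assumed diameter,
and the skeleton graph yields connection counts.

## Processing pipeline

**Vesselness.** A single-scale 2D Frangi filter with σ = 1 px (smoothing
FWHM 2.35 px) is applied per slice. One scale suffices because canaliculi
are nearly homogeneous in apparent diameter at this sampling (200 nm/px);
filtering in-plane (not 3D) is deliberate: the axial PSF is ~4× wider than
the lateral one, so in-plane Hessian geometry carries essentially all the
tube contrast. Boundary handling is reflective, avoiding spurious edge
ridges. The blobness sensitivity β defaults to 0.5 and the structureness
scale c to "auto" (half the maximum Hessian Frobenius norm per slice) — the
conventional defaults of the widely used implementation of this filter;
both are exposed in the config. Before differentiation the slice mean is
subtracted so a constant slice yields exactly zero response.

**Segmentation.** Hysteresis thresholding of the whole response volume:
components of {v ≥ t_low} are kept iff they contain a voxel with
v ≥ t_high, with 3D 26-connected linking (the volume is segmented as a
whole; 2D within-slice linking is available). In the original workflow the
two thresholds were chosen by visual examination; the reproducible
surrogate used here derives them from the response histogram. Histogram
rules tied to the bulk of the distribution (fixed percentiles, Otsu) are
density-dependent — the tube footprint shifts the whole histogram — so the
default anchors both thresholds on the 99.9th percentile of the nonzero
response, which lies inside the brightest tubes and is nearly invariant
(±5 %) across canalicular fractions of 0.5–1.5 %: t_high = 0.15 × anchor
(seeds) and t_low = 0.03 × anchor (linking). The two fractions were
calibrated once on phantoms with known ground truth, as the operational
stand-in for the visual choice; percentile/Otsu modes and absolute
overrides remain available. Segmented components of ≤ 8 voxels are
discarded, replacing the manual removal of isolated noise artifacts.

**Lacunae.** Lacunae are segmented on the *raw* intensity: threshold →
slice-wise 2D disk erosion (2 px, which removes canaliculi) → dilation
(3 px, restoring lacunar volume) → 26-connected labeling, discarding
components below 20 µm³. The threshold default is the upper split of a
3-class Otsu ("multiotsu"): the intensity histogram genuinely has three
classes (background, canaliculi, lacunae), and a 2-class Otsu can land
between background and canaliculi in dense networks, flooding the mask.
Slice-wise disks rather than 3D balls: the axial PSF already smears
lacunae in z, so 3D structuring elements would be needlessly aggressive
axially. The lacuna mask is subtracted from the segmented network before
skeleton analysis, since vesselness-filtered lacuna rims otherwise
generate artificial segments and connections.

**Skeleton and graph.** The segmented network is thinned by
topology-preserving 3D medial-axis thinning (26-connected foreground). The
thinning backend can erase small compact components entirely; these are
restored as their innermost voxel so the connected-component count is
exactly preserved. Skeleton voxels are classified by 26-neighbor count
(< 2 endpoint, = 2 slab, > 2 junction); adjacent junction voxels merge
into one junction node, slab chains become branches, and branch length is
the anisotropic voxel-center polyline length (plus the step onto each
attached junction voxel). No spline smoothing is applied.

Two cleanup steps address skeleton artifacts of noisy, PSF-broadened
tubes, and both are applied identically to any reference skeleton they are
compared against:

* *Terminal-twig pruning* (`min_branch_um`, default 0.8 µm): endpoint
  branches shorter than the optical resolution are noise twigs; after
  pruning, a junction left with fewer than three branches is reclassified
  as a pass-through point.
* *Resolution-scale junction merging* (`junction_merge_radius_um`, default
  1.5 µm ≈ the axial FWHM): junctions joined by branches shorter than the
  resolution are optically indistinguishable and are counted as one
  connection; the connecting rungs keep contributing to the total length
  but not to the canaliculus count.

**Indicators.** Over an analyzed volume TV (total imaged volume, lacunae
included — whether lacunar porosity should be excluded from TV is left as
a convention; we do not exclude it):

* `Ca.V/TV (%) = 100 · L · π (d/2)² / TV`, with L the total skeleton
  length and d = 0.2 µm the assumed canalicular diameter (an upper bound
  for mice; config-exposed).
* `N.Connect/TV = n_junctions / TV × 10⁹` (mm⁻³); the junction-voxel
  fraction (junction voxels / grid voxels, %) is reported as an auxiliary
  "connection density" surrogate, since that quantity is not otherwise
  standardized.
* `N.Lc/TV = n_lacunae / TV × 10⁹` (mm⁻³).
* "Number of canaliculi" is the branch count of the graph, terminal
  branches included, loops counted once.

**Orientation.** The 2D FFT modulus of the vesselness-filtered slices
(averaged over the stack by default; a z-projection mode exists) is
integrated over a radial band of 10–80 % of Nyquist (excluding DC and the
PSF-dominated rim) in 36 angular bins folded to [0°, 180°). The
anisotropy index is the resultant length of the doubled-angle
distribution (0 = isotropic, 1 = single orientation). Morphology labels
are operational surrogates for a qualitative reading: *butterfly* if a
secondary folded peak sits at 90° ± 15° from the primary with ≥ 0.3 of
its height, else *isotropic* if the anisotropy index is < 0.1, else
*bimodal*; ambiguity resolves butterfly > bimodal > isotropic.

**Statistics.** Signed relative errors against a reference skeleton are
reported as nearest-integer percentages (half away from zero), per metric
and per variant (with/without lacuna mask). Group comparison uses
classical one-way fixed-effects ANOVA (the only omnibus test; no post-hoc
corrections). Required group sizes use the two-sample normal-approximation
formula with unequal variances,
`n = ⌈(z₁₋α/₂ + z_power)² (σ₁² + σ₂²) / δ²⌉`, with "p-values of 0.05 and
0.10" interpreted as two-sided significance levels at default power 0.80;
a fractional effect is δ = fraction × stated mean. Because published
group-size tables of this kind are rarely reproducible exactly from
rounded inputs, the package also ships a Monte-Carlo oracle
(`empirical_power`: Welch t-tests on simulated cohorts) so any returned n
can be verified directly; the formula's n achieves the target power within
the normal-approximation slack (~0.05) in these simulations.

## The phantom generator

The generator produces ground truth first, then an image:

* **Lacunae**: triaxial ellipsoids, semi-axes drawn from configurable
  ranges (default ~1.9 × 1.9 × 4.2 µm half-axes, major axis in-plane),
  placed by hard-core rejection (bounding spheres disjoint) at a target
  number density (default 7×10⁴ mm⁻³). Quantitative lacunar morphometry
  is *not* a goal; these dimensions are placeholders with the right order
  of magnitude, not measured ground truth.
* **Canaliculi**: persistent random walks (step 0.8 µm, direction blended
  60/40 with a regime sample) seeded on lacuna surfaces; they terminate on
  reaching another lacuna, the volume boundary, or a maximum length
  (22 µm), and spawn perpendicular side branches with probability 0.10
  per step. Growth stops when the total centerline length meets the
  budget `L = (f/100)·V/(πr²)` implied by the target volume fraction f
  (default 1 %, radius r = 0.1 µm) — realized length lands within one
  step of the budget, far inside the 5 % contract.
* **Orientation regimes**: step directions are mostly in-plane (thin
  sections). *isotropic* draws uniformly (z damped); *bimodal* draws the
  in-plane angle from a von Mises lobe of concentration κ (default 8)
  about a configurable axis; *butterfly* assigns each canaliculus to the
  orthogonal family with probability w/(1+w) (default w = 0.35). The lobe
  is fixed per canaliculus — mixing families per growth step would produce
  diagonal meanders instead of two tube populations. These regimes
  reproduce circular, two-lobed and lobes-plus-orthogonal-streak angular
  spectra respectively.
* **Rasterization**: a voxel is canal iff its center lies within r of a
  centerline (computed by a distance transform from finely sampled
  centerline voxels), and lacuna iff its center is inside an ellipsoid.
  The truth skeleton graph is built directly from the polylines, so its
  lengths carry no voxelization error.
* **Rendering**: intensity = Poisson[scale · blur(A·(canal ∪ lacuna) +
  background)] / scale, with a separable Gaussian PSF of FWHM 0.43 µm
  (lateral) and 1.8 µm (axial), and a background field = mean 12 +
  band-limited Gaussian fluctuation (SD 4, correlation length 2 µm)
  emulating the fluctuating matrix signal. Defaults A = 900 and
  scale = 1 photon per intensity unit leave a blurred on-tube peak
  around 4× the local background SD — visible but noisy, consistent
  with photon-counting detection of sub-resolution tubes against a
  strong matrix background. Shot-noise scale 0 disables noise (ideal
  detector), used for reference renders and determinism tests.

Everything is deterministic under a fixed seed: identical parameters give
bit-identical ground truth, masks and images.

### What phantom validation shows — and what it does not

Ground truth for the recovery tests is taken per quantity from the most
defensible reference:

* *Ca.V/TV*: the analytic generative length (exact).
* *Lacuna count*: the generated ellipsoid count (exact).
* *Connections*: the junction count of the skeletonized **clean** canal
  mask (lacunae removed, no noise, no blur), measured with the same graph
  machinery and cleanup as the pipeline output. Connectivity has no
  resolution-free definition: canaliculi that physically touch at voxel
  scale are genuinely connected pores, so the voxelized clean network —
  not the generative branch list — is the honest connectivity reference.

On phantoms at 0.5 / 1.0 / 1.5 % canalicular fraction the full pipeline
recovers Ca.V/TV within 25 % relative, connection counts within 30 %,
and lacuna counts exactly; this is commensurate with the 10–20 % errors
reported for this processing approach against manually corrected
reference skeletons on real data. The Ca.V/TV error grows with density
(about −7 % at 0.5 %, −18 % at 1.0 %, −24 % at 1.5 % fraction): tubes
closer than the PSF merge and skeletonize to a single centerline, an
imaging-resolution effect — even an ideal noise-free segmentation of the
voxelized truth loses ~15 % of the length at 1.5 % fraction. The phantoms do **not** model coherent
THG signal buildup (signal strength vs tube orientation and diameter),
air-bubble artifacts, polishing damage, or spatially varying aberrations;
passing these tests therefore demonstrates the soundness of the image
*processing*, not of the imaging process itself.

## Problem sizes

Phantom validations use the 64 × 64 × 12 µm³ analysis volume at
300 × 200 × 200 nm voxels (40 × 320 × 320), the same region size used for
uncertainty estimation on real data; fast unit tests use 24 × 24 × 6 µm³
phantoms. Monte-Carlo power checks use 5000 replicates; ANOVA calibration
1000 replicates.

## Known limitations

* The hysteresis low/high ratio and the junction cleanup radii were
  calibrated on phantoms rendered with this generator; stacks with very
  different background statistics may need the config overrides.
* Junction counts depend on the cleanup conventions (twig pruning, merge
  radius); comparisons across studies are only meaningful under identical
  settings, which is why every parameter is recorded in the run manifest.
* The "connection density (%)" column reports the junction-voxel fraction,
  an auxiliary surrogate for a quantity with no standard definition.
* Lacunar shape morphometry is out of scope; the lacuna model exists to
  exercise the masking logic, not to be measured.
* Mosaic stitching of tiled acquisitions is out of scope: the pipeline
  consumes single stacks.
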