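# lcnquant

Quantification of the bone **lacuno-canalicular network (LCN)** from
label-free 3D microscopy stacks.

Osteocytes sit in µm-scale cavities (lacunae) connected by ~200 nm channels
(canaliculi); this porosity network is a structural readout of bone
mechanobiology. Third-harmonic generation (THG) microscopy resolves the LCN
without staining, but the mineralized matrix contributes a strong,
spatially fluctuating background, so extracting network statistics needs a
dedicated processing pipeline. `lcnquant` implements that pipeline as a
tested, reusable library:

1. **Vesselness filtering** — single-scale 2D Frangi filter (σ = 1 px,
   FWHM 2.35 px) applied slice-by-slice to enhance tubular canaliculi:
   with Hessian eigenvalues |λ₁| ≤ |λ₂|,
   `v = exp(−R_B²/2β²)·(1 − exp(−S²/2c²))`, `R_B = λ₁/λ₂`,
   `S = √(λ₁²+λ₂²)`, zero where λ₂ > 0 (bright tubes).
2. **Hysteresis segmentation** of the whole response volume (dual
   threshold, 26-connected linking).
3. **Lacuna analysis** — threshold → erode (removes canaliculi) → dilate
   (restores lacunar volume) → count; the mask also excludes lacunar
   voxels from canalicular analysis.
4. **Skeletonization and graph analysis** — topology-preserving 3D
   thinning, endpoint/junction/branch decomposition with anisotropic
   branch lengths.
5. **Network indicators** — canalicular volume fraction
   `Ca.V/TV (%) = 100·L·π(d/2)²/TV` (total skeleton length L, assumed
   diameter d = 200 nm), connection density `N.Connect/TV` (mm⁻³), lacuna
   density `N.Lc/TV` (mm⁻³).
6. **Orientation descriptors** — angular power of the 2D FFT modulus of the
   filtered images, with an anisotropy index and a morphology label
   (isotropic / bimodal / butterfly).
7. **Validation and group statistics** — signed percent error reports
   against a reference skeleton, one-way ANOVA across animal groups, and
   two-sample sample-size estimation
   `n = ⌈(z₁₋α/₂ + z_power)²(σ₁²+σ₂²)/δ²⌉` with a Monte-Carlo power oracle.

Because real THG stacks of this kind are not publicly deposited, the
package ships a **synthetic phantom generator** (`lcnquant.phantom`):
ellipsoidal lacunae placed as a hard-core process, canaliculi grown as
persistent random walks with configurable orientation regimes, rendered
with the instrument's anisotropic PSF (0.43 µm lateral / 1.8 µm axial),
a band-limited fluctuating matrix background and Poisson shot noise.
Every pipeline stage is validated against this known ground truth.

## Worked example

```python
from lcnquant import GenerationParams, PipelineConfig, run_pipeline
from lcnquant.phantom import simulate

# a 64 x 64 x 12 um^3 THG-like phantom: 1% canalicular fraction,
# 7e4 lacunae per mm^3
image, canal, lacuna, truth_skel, gt = simulate(GenerationParams(seed=2))
result = run_pipeline(image, PipelineConfig(seed=2))
row = result.metrics_row()
print(f"Ca.V/TV    = {row['cav_tv_pct']:.2f} %")
print(f"N.Lc/TV    = {row['nlc_tv_e4_mm3']:.1f} x 1e4 mm^-3")
print(f"N.Connect  = {row['nconnect_tv_e7_mm3']:.1f} x 1e7 mm^-3")
print(f"morphology = {row['orientation_label']}")
```

prints

```
Ca.V/TV    = 0.82 %
N.Lc/TV    = 6.1 x 1e4 mm^-3
N.Connect  = 1.7 x 1e7 mm^-3
morphology = bimodal
```

i.e. the pipeline recovers the 1 % ground-truth canalicular volume
fraction within its ~20 % processing uncertainty and the lacuna density
exactly (3 lacunae in 49 152 µm³ = 6.1×10⁴ mm⁻³), both inside the healthy
murine cortical-bone ranges (0.5–1.5 % and 6–8×10⁴ mm⁻³).

The numbered scripts under `analysis/` run the full study at desk scale:

```bash
python analysis/01_simulate_phantoms.py      # phantom set -> scratch/, truth table -> results/
python analysis/02_pipeline_uncertainty.py   # pipeline-vs-truth error tables
python analysis/03_orientation_survey.py     # angular spectra per orientation regime
python analysis/04_group_statistics.py       # uncertainty arithmetic + group sizes
```

A command-line interface exposes each stage
(`lcnquant simulate|filter|segment|skeletonize|metrics|orientation|validate|stats|run`).

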