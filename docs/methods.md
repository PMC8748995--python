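# Methods

`octquant` implements a quantitative pipeline that links tissue optical
properties measured by serial block-face optical coherence tomography (OCT)
to the two dominant structural sources of scattering in brain tissue —
myelin content and neuronal cell bodies — via a generalized linear model.
Because no public brain dataset accompanies this kind of study, the package
ships a first-class synthetic-data generator that produces co-registered
phantoms with known ground truth; every downstream stage is validated
against it.

## 1. Optical model and attenuation fitting

A single OCT A-line records backscattered intensity versus depth.  Under
the single-scattering Beer–Lambert approximation,

    R(z) = mu_b' · exp(−2 mu_s z) · h(z) · H(z)

with

* `mu_s` — scattering coefficient (mm⁻¹), the quantity of interest;
* `mu_b'` — relative back-scattering coefficient, absorbing source power,
  spectrometer efficiency and detection geometry (relative units);
* `h(z) = 1 / (1 + ((z − Zf)/ZRs)²)` — confocal weighting of the objective
  with focus depth `Zf` and effective Rayleigh range `ZRs` (µm);
* `H(z)` — spectrometer sensitivity roll-off.

Absorption is ignored (negligible at 1300 nm in fixed tissue).  The
functional form of `H(z)` is an open choice for spectral-domain systems; we
default to `exp(−z / rolloff_decay)` with a disable switch, and the
simulator and the fitter share the same form so no model mismatch is
introduced by default.  Mismatch experiments are possible but are not part
of the shipped validation.

**Estimation.**  A-lines are averaged over a 30 × 30 µm² lateral block
before fitting; fully developed speckle is multiplicative with unit mean,
so block averaging reduces its relative standard deviation as 1/√N.  Each
averaged A-line is then fitted in the linear-intensity domain by
trust-region least squares (`scipy.optimize.least_squares`, analytic
Jacobian) with only two free parameters, `mu_s ∈ [0, 50] mm⁻¹` and
`mu_b' ≥ 0`.  The bounds bracket reported brain values (≈1–12 mm⁻¹) with
wide margin.  `Zf` and `ZRs` are *not* fitted per A-line — they are
strongly inter-dependent with `mu_s` — but pre-calibrated once per volume
on a homogeneous Intralipid-like phantom of known `mu_s` (pooled mean
A-line, three free parameters: `Zf`, `ZRs` and a nuisance amplitude).
A constant `(Zf, ZRs)` per volume is an explicit simplification; a
laterally varying parameterization is left as future work.

Starting values come from a log-linear regression of the windowed profile
(slope → `mu_s`, intercept → `mu_b'`), after dividing out the known
confocal and roll-off factors.  Whether real systems fit in linear or log
intensity varies; linear-domain least squares is our documented choice.

**Fit window.**  The tissue surface is the first sample exceeding 20% of
the profile maximum (first crossing breaks ties); the fit uses
[30, 450] µm below that surface and requires ≥ 10 samples.  Failed pixels
(no surface, short window, non-convergence) are masked in the output maps,
never fatal.

**Units and coordinates.**  Lengths are µm at every interface and `mu_s`
is mm⁻¹; the 1 mm = 1000 µm conversion happens in exactly one constant.
Depth sample k is at `z = k · z_spacing`; lateral map pixel (i, j) is
centred at `((j + 0.5)·pitch, (i + 0.5)·pitch)`.  The nominal axial pitch,
2.9 µm, is the 1.5 mm imaging depth divided over 1024/2 spectrometer
pixels.

## 2. Histology quantification

**Gallyas OD (myelin).**  Stain darkness is converted to mean decadic
optical density per pixel: `OD = −(1/3) Σ_{R,G,B} log10(I_i / 255)`.
Zero-intensity channels are clipped at OD 3.0 (the 8-bit floor) to avoid
infinities.  Optional per-channel percentile normalisation (defaults 1–99)
rescales real slides with uncontrolled illumination; it is **off** by
default in the pipeline because the synthetic slides are rendered with a
calibrated intensity↔OD relation and normalisation would destroy the OD
scale (and hence the regression slope).

**Nissl COPA (cell bodies).**  Under Mie scattering with a constant phase
function `Qs`, the cellular contribution to `mu_s` is proportional to
`Ns · As` (number density × cross-sectional area).  Cellular occupation
per area (COPA) measures exactly this: cell bodies are segmented by
thresholding the grayscale OD image (Otsu by default; a fixed threshold is
available because real staining is variable), components smaller than
50 µm² are removed — excluding glia (~2.5 µm radius) while keeping neuron
somata (≥ ~4 µm radius) — and the occupancy fraction is evaluated in a
sliding 200 × 200 µm box.  The box stride defaults to 30 µm so the COPA
grid aligns with the block-averaged `mu_s` maps; boxes truncated at image
borders use in-bounds pixels only.  Overlapping somata are unioned in the
mask, which underestimates occupancy in dense regions; the generator's
default placement is non-overlapping, consistent with the assumption that
somata do not overlap on thin sections.

## 3. The scattering GLM

Per-region circular ROIs are averaged in each map (a pixel belongs to an
ROI when its centre lies inside the circle) and assembled into a table of
`(mu_s, OD, COPA)` means with tissue-class labels.  The model is

    mu_s = b + k1 · OD + k2 · COPA

with COPA forced to 0 on white-matter rows before regression (white matter
contains essentially only glia) and a single `(b, k1)` shared between grey
and white matter; a per-class relaxation is available but non-default.
Although the coefficient estimate is the normal-equations pseudoinverse
`β = (XᵀX)⁻¹ Xᵀ y`, the implementation solves via QR for conditioning and
is tested to agree with the pseudoinverse to 10⁻¹⁰ on well-conditioned
designs.  Rank-deficient designs raise a collinearity error naming the
offending columns.

Diagnostics: squared Pearson correlation R² of (y, ŷ); NRMSE defined as
RMSE / range(y) (a documented dialect — mean(y) normalisation is a
one-line switch); partial correlation coefficients computed by the
residual-regression definition; per-coefficient two-sided t-tests with
n − p degrees of freedom, with Bonferroni correction across the
coefficients of a model (the exact multiple-comparison procedure used in
practice varies; Bonferroni is the conservative default and is
configurable).  Four univariate back-scattering screens fit `mu_b'` and
`mu_b'/mu_s` each against OD and COPA; no multivariate variant is fitted
for them.

## 4. The synthetic-data generator

The generator emulates a cortical column imaged by block-face OCT and
stained nearby sections:

* **Geometry** — flat horizontal bands (default: supragranular, granular,
  infragranular grey plus white matter, 406 µm each, 870 µm wide at
  2.9 µm pitch).  Real cortex is curved; curvature adds registration
  complexity that the GLM does not need, so it is deliberately absent.
* **Ground truth** — per-layer myelin density on the OD scale (0.25, 0.45,
  0.65, 1.0) and neuron densities (1000, 1400, 640 mm⁻²; somata radius
  7 ± 1 µm, glia 2.5 µm) chosen so COPA spans ≈ 0.10–0.22 and is *not*
  an affine function of OD across layers, keeping `k1` and `k2` separately
  identifiable.  `mu_s` follows the GLM with default coefficients
  `(b, k1, k2) = (1.0, 7.2, 5.0)` — the pooled myelin slope scale reported
  for human cortex — plus residual heterogeneity, and
  `mu_b' = 0.1 + 0.2 · mu_s` (back-scattering tracks scattering).
* **OCT volume** — the forward model above, per voxel, with fully
  developed speckle as i.i.d. unit-mean exponential multiplicative
  intensity noise.  Exponential intensity statistics are the standard OCT
  assumption and make the 1/√N averaging rationale testable.  Noiseless
  volumes are evaluated in double precision and are bit-identical to
  `model_profile`; speckled volumes use a single-precision cumulative
  product along depth (relative rounding ~10⁻⁶, three orders below the
  speckle).
* **Slides** — Gallyas intensity `255 · 10^(−OD·gain)` with log-normal
  staining jitter (default sd 0.005 OD, mimicking minor staining
  variability) quantised to 8 bits at 1.9 µm pitch; Nissl as dark
  elliptical somata (aspect 0.75–1, area-preserving) plus paler glia disks
  on a pale background, with the exact neuron raster mask returned as
  segmentation ground truth (glia are rendered but excluded from it).
* **Self-consistent COPA** — in the linked dataset the *realised*
  occupancy of the rendered somata (200 µm box) replaces the analytic
  density × area value before `mu_s` is formed, so each pixel's scattering
  reflects the cells actually present there.  This removes an
  errors-in-variables attenuation of `k2` that would otherwise be an
  artifact of the phantom, not of the method.
* **Residual mu_s noise** — sd 0.3 mm⁻¹ (~4% of white-matter `mu_s`),
  drawn on a 30 µm grid so that, like real tissue heterogeneity, it
  survives block averaging instead of vanishing as 1/√N.  No reference
  SNR for averaged A-lines is available, so the noise levels are free
  parameters of the phantom, fixed here once.
* **ROIs** — ~20 non-overlapping circles per layer, radius 21.5–23.9 µm
  (≈ 400–500 histology pixels in area, the documented ROI size range),
  rejection-sampled with margins: half a COPA box from grey-layer
  boundaries (so occupancy neighbourhoods do not straddle layers) and one
  block from the lateral edges (so every ROI lies inside the fitted-map
  footprint).  The lower end of the radius range guarantees that at least
  one 30 µm map-pixel centre falls inside every ROI.  Real studies draw
  such ROIs manually; programmatic placement is the testable surrogate.

What the phantom does **not** emulate: cortical curvature, tile stitching
and blending, fibre-orientation effects on `mu_b'`, slice distortion and
staining gradients, spatially varying focus.  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-world effects.

## 5. Problem sizes and determinism

The shipped validation uses phantoms of 870 × 1624 µm laterally (2.9 µm
pitch) and 600 µm depth — 300 × 560 × 207 voxels, yielding a 30 × 56 block
grid of fits and 80 ROIs — a size chosen so that a 100-replicate
coefficient-recovery experiment (95% CI coverage of each of b, k1, k2,
observed ≥ 95/100) runs on a single CPU in a few minutes.  Calibration
phantoms pool 100 A-lines (validation) or 150 × 150 A-lines (pipeline
default, keeping the propagated `Zf`/`ZRs` error well below the
coefficient standard errors).  All generators are pure functions of
(specification, seed): one `SeedSequence`-derived stream per stage,
bit-identical outputs for identical inputs, byte-identical `summary.json`
for identical configs.

## 6. Known limitations

* Constant `(Zf, ZRs)` per volume; no lateral focus variation.
* `H(z)` is a modelling choice, not a measured curve; fitter and simulator
  share it by construction.
* Otsu thresholding assumes a bimodal OD histogram; heavily counterstained
  slides may need the fixed-threshold mode.
* The union rule for overlapping somata underestimates COPA in very dense
  regions (the generator's non-overlapping default sidesteps this; real
  dense tissue does not).
* OLS inference assumes homoscedastic ROI-level residuals; speckle-driven
  fit noise actually scales with `mu_s`, which mildly violates this.  The
  observed CI coverage (≈95%) indicates the effect is small at the default
  noise levels.
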