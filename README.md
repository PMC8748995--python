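# octquant

**Quantitative OCT optical properties linked to myelin content and neuron
density in brain tissue.**

Serial block-face optical coherence tomography (OCT) measures intrinsic
tissue optical properties — the scattering coefficient `mu_s` and the
relative back-scattering coefficient `mu_b'` — label-free and in 3D.  In
the human brain, scattering is dominated by myelin, with neuronal cell
bodies a secondary contribution, which makes `mu_s` a candidate objective
measurement of myelin content (and, more weakly, of neuron density) for
architectonic mapping and for studying demyelinating and neurodegenerative
disease.  `octquant` implements the full quantitative chain that puts this
on a regression footing, for researchers working with block-face OCT
volumes and adjacent stained sections:

1. **Attenuation fitting** (`octquant.oct`) — per-A-line nonlinear least
   squares of the depth profile

       R(z) = mu_b' · exp(−2 mu_s z) · h(z) · H(z),
       h(z) = 1 / (1 + ((z − Zf)/ZRs)²)

   with 30 × 30 µm² block averaging of speckle, confocal parameters
   (Zf, ZRs) pre-calibrated on a homogeneous phantom of known `mu_s`, and
   derived maps (`mu_b'/mu_s` ratio, average intensity projection).
2. **Histology quantification** (`octquant.histology`) — Gallyas silver
   stain to mean optical density, `OD = −(1/3) Σ log10(I_i/255)` (myelin);
   Nissl stain to cellular occupation per area (COPA): threshold
   segmentation, < 50 µm² glia removal, sliding 200 × 200 µm occupancy.
3. **The scattering GLM** (`octquant.glm`) — ROI means of the three maps
   fitted as

       mu_s = b + k1 · GallyasOD + k2 · COPA,
       beta = (XᵀX)⁻¹ Xᵀ mu_s

   with COPA forced to zero in white matter, partial correlations, R²,
   NRMSE, coefficient t-tests, univariate-vs-multivariate comparison,
   per-region summaries, and four univariate `mu_b'` screens.
4. **Synthetic ground truth** (`octquant.synthetic`) — layered cortical
   phantoms with speckled OCT volumes, Gallyas-like and Nissl-like slides
   and programmatic ROIs, all tied to known GLM coefficients, so the whole
   pipeline is testable end to end without external data.

See `docs/methods.md` for the model, its assumptions and all numerical
choices.

## Worked example

Run the end-to-end pipeline (simulate → calibrate → fit-oct → histology →
GLM) on the default four-layer phantom, generated with true coefficients
`(b, k1, k2) = (1.0, 7.2, 5.0)`:

```bash
octquant report --seed 7 --out runs/demo
```

which prints

```
recovered (b, k1, k2) = [0.911, 7.229, 5.655] (truth [1.0, 7.2, 5.0]), R^2 = 0.979
```

and writes maps (`mu_s.tif`, `mu_b.tif`, `ratio.tif`, `aip.tif`,
`od.tif`, `copa.tif`), stain images, the ROI table and `summary.json`.
From that summary for this seed:

| quantity | value | meaning |
|---|---|---|
| `beta` | 0.911, 7.229, 5.655 | intercept (residual scattering), myelin slope k1 (mm⁻¹ per OD), cell slope k2 (mm⁻¹ per COPA) |
| `ci95` (od) | [6.863, 7.595] | covers the generating k1 = 7.2 |
| `pcc` | od 0.976, copa 0.713 | myelin dominates `mu_s`; cells are secondary |
| `r2`, `nrmse` | 0.979, 0.041 | goodness of the 80-ROI multivariate fit |
| `calibration` | Zf 300.0, ZRs 120.2 µm | phantom-recovered confocal parameters (truth 300, 120) |
| screens `r2` | `mu_b` vs OD 0.946; `ratio` vs OD 0.764 | `mu_b'` inherits the OD relation through `mu_s`; the ratio decouples |

The individual stages are available as subcommands (`simulate`,
`calibrate`, `fit-oct`, `histo-od`, `histo-copa`, `glm`), each taking
`--seed`, `--config` (YAML, unknown keys rejected) and `--out`, or as
plain library calls:

```python
from octquant import SystemConfig, model_profile, fit_profile
import numpy as np

cfg = SystemConfig(zf=300.0, zrs=120.0, rolloff_decay=None)
z = np.arange(207) * 2.9                      # um
profile = model_profile(8.0, 1.5, z, cfg)     # mu_s mm^-1, mu_b' rel.
fit = fit_profile(profile, cfg)
print(fit.mu_s, fit.mu_b_rel)                 # 8.000 1.500
```

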