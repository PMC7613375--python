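# hytrait

Hybrid retrieval of crop traits from hyperspectral reflectance: simulated
training libraries, diversity-based active learning, Gaussian process
regression with automatic relevance determination, and per-pixel trait +
uncertainty mapping.

## What problem this solves

Imaging spectrometers (PRISMA today, CHIME soon) deliver contiguous
400–2500 nm reflectance at ~10 nm sampling.  Turning those spectra into
maps of vegetation traits — specific leaf area (SLA), leaf area index
(LAI), canopy chlorophyll and water content (CCC, CWC), FAPAR and
fractional vegetation cover (FVC) — is usually done with *hybrid* models: a
radiative-transfer simulator generates (spectrum, trait) training pairs and
a machine-learning regressor inverts them on real data.  Two practical
obstacles are the size of the simulated pools and the extreme band-to-band
collinearity of hyperspectral data.  `hytrait` implements the full
workflow:

1. **Simulator** — a lightweight surrogate canopy model (Beer–Lambert
   absorption features, gap-fraction soil/vegetation mixing, weak BRDF
   modulation) that generates trait-labeled libraries, zero-labeled
   non-vegetated spectra, and synthetic scenes with per-pixel truth.
2. **Spectral tools** — Gaussian spectral-response resampling to
   instrument grids, atmospheric exclusion windows, CSV/ENVI/GeoTIFF I/O.
3. **Active learning** — Euclidean-distance-based diversity (EBD)
   selection with a strict accept-if-improved rule against a reference
   set: `d_E(u, l) = ‖x_u − x_l‖²`, propose `argmax_u min_l d_E`, keep the
   candidate only if reference RMSE decreases.
4. **GPR** — Gaussian process regression with the ARD Rational Quadratic
   kernel

   `K(x_i, x_j) = σ_f² (1 + 1/(2α) Σ_m (x_im − x_jm)²/σ_m²)^(−α)`,

   trained by evidence maximization with analytic gradients; predictions
   carry the analytic mean `μ* = k*ᵀ(K + σ_n²I)⁻¹y` and variance
   `σ*² = k** − k*ᵀ(K + σ_n²I)⁻¹k*`.  Fitted lengthscales double as band
   relevance `r_m = 100(1 − σ_m²/max σ_m²)`.
5. **Dimensionality reduction** — PCA with a cumulative-variance rule
   (99.95%) or a fixed 20 components, versus sequential backward band
   removal (SBBR): drop the band with the largest lengthscale by 3-fold
   cross-validated consensus, retrain, repeat down to one band.
6. **Workflow** — the two strategies (`GPR-20PCA`, `GPR-20BR`) end to end,
   plus per-pixel mapping with SD and CV% uncertainty layers.

## Worked example

`python examples/04_map_traits.py` trains both strategies for FVC on a
600-sample simulated pool (40 nm demo grid) and maps a 40×40 synthetic
scene containing vegetated, soil and water pixels:

```
GPR-20PCA: vegetated R2 0.990, RMSE 0.0246; mean |estimate| on water 0.0002; mean predictive SD 0.0254
GPR-20BR: vegetated R2 0.994, RMSE 0.0219; mean |estimate| on water 0.0026; mean predictive SD 0.0072
PCA-vs-BR map consistency: R2 0.997, bias +0.0072
```

Vegetated pixels track the simulated truth, non-vegetated pixels map to
~0 because 26 zero-labeled soil/water/man-made spectra are appended to
every training set, and the two reduction strategies agree closely.  The
other examples cover library simulation (`01`), active learning versus a
random subset (`02`), and band ranking with the relevance polar table
(`03`).

There is also a thin CLI:

```sh
hytrait simulate --n 2000 --seed 7 --out lib.csv
hytrait train --variable FVC --strategy pca --pool lib.csv --out model.json
hytrait map --bundle model.json --cube scene.img --out fvc.tif
```

## Layout

```
src/hytrait/     simulator, spectral, gpr, active_learning, dimred,
                 evaluation, workflow, cli
examples/        one narrative script per capability
tests/           unit + property + acceptance suites
docs/methods.md  models, assumptions, parameter choices, limitations
```
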