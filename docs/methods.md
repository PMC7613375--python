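# Methods

This note documents the models inside `hytrait`, the choices behind their
parameters, and what the synthetic experiments do and do not demonstrate.

## The surrogate canopy simulator

Physically rigorous simulators couple leaf biochemistry, canopy structure,
soil optics and sun–sensor geometry through full radiative transfer.
`hytrait` deliberately replaces that machinery with a closed-form surrogate
whose job is statistical, not radiometric: it must produce trait-driven,
strongly collinear, nonlinear reflectance spectra so that the downstream
methodology (active learning, ARD-GPR, PCA vs band ranking) is exercised
under realistic conditions.

**Leaf level.** Specific absorption coefficients are sums of Gaussians at
the known feature positions — chlorophyll 430/660 nm, carotenoids 470 nm,
water 970/1200/1450/1940 nm, dry matter 1730/2100/2300 nm.  The leaf
optical depth is `a(λ) = (C_ab k_ab + C_xc k_xc + C_w k_w + C_m k_m)/N`,
absorptance `A = 1 − exp(−a)` (Beer–Lambert), and reflectance
`ρ_leaf = ρ₀ + s_N (1 − A)` with `s_N = s₀ + s₁(N − 1.5)`.  The scattering
constants (ρ₀ = 0.02, s₀ = 0.46, s₁ = 0.05) put the NIR plateau near
0.45–0.5, typical of green leaves.

**Canopy level.**  The nadir gap fraction is `P = exp(−k_ext · LAI)` with
`k_ext = 0.5(1 + 0.3·LIDF)` — 0.5 is the standard nadir extinction of a
spherical leaf-angle distribution, and the LIDF term makes extinction
respond to leaf inclination.  Canopy reflectance mixes leaf and soil by
gap fraction, with a multiple-scattering gain `1 + q(1 − A)` (q = 0.8)
that brightens weakly absorbing regions, and a weak geometric modulation
`g_geo = 1 + 0.05(cos OZA − 1) + 0.02 cos RAA sin SZA sin OZA` standing in
for BRDF effects.  Output is clipped to [0, 1].

**Soil.**  `R_soil = α_soil · B_soil · r₀(λ) · (1 − 0.7(SMC/100) w̄(λ))`,
where `r₀` rises linearly 0.10 → 0.35 over 400 → 2400 nm and `w̄` is the
max-normalized water-absorption shape (moist soils darken most where water
absorbs).  The soil-position variables (latitude/longitude of the
brightness–shape–moisture parameterization) are sampled to honor the input
table but are spectrally inert — a documented limitation.

**Input distributions.**  Leaf biochemistry uses truncated Gaussians
(e.g. chlorophyll mean 45, SD 35 on [0, 80] μg/cm²; dry matter mean
0.0075, SD 0.005 on [0.002, 0.02] g/cm²), structure and geometry use
uniforms (LAI on [0.1, 8] m²/m², angles over the acquisition envelope).
Truncated Gaussians are realized by rejection sampling rather than
clipping, so no probability mass piles up at the bounds.  The default pool
size is 2000 samples.

**Derived targets.**  `SLA = 1/C_m` (cm²/g), `CCC = LAI·C_ab·10⁻²` and
`CWC = LAI·C_w·10⁴` (g/m²), `FVC = 1 − P`.  FAPAR is defined as
interception times mean PAR absorptance, `(1 − P)·mean_{400–700} A(λ)` — a
surrogate for an energy-balance computation, chosen because it is exact in
both limits (zero canopy, black canopy) and guarantees `FAPAR ≤ FVC`.

**Non-vegetated spectra.**  Four archetypes (bright/dark soil: smooth
convex; water: low with SWIR near zero; man-made: flat gray) with
multiplicative level and smooth spectral jitter; all trait labels are zero.
Default augmentation size: 26 spectra per training set.

**Synthetic scenes.**  Trait fields are low-frequency random surfaces
(Gaussian-smoothed noise mapped through each input's marginal quantile), a
spatially coherent ~20% of pixels get non-vegetated archetypes with zero
truth.  With `fine_step` set, scene spectra go through the same fine-grid
simulation + Gaussian-SRF resampling as training pools, so models never
see a systematic band-convolution mismatch between library and scene.

**What passing tests do not show.**  The surrogate has no anisotropic hot
spot, no senescent material, no atmospheric residuals, and its nuisance
dimensionality is lower than nature's.  Synthetic successes therefore
bound the *methodology* (sampling, reduction, regression, uncertainty),
not retrieval accuracy on real scenes.

## Spectral resampling and exclusion

Instrument bands are Gaussian spectral response functions characterized by
center and FWHM.  Resampling is the SRF-weighted mean over source samples
within ±2 FWHM, renormalized — exact for constant spectra, linear by
construction, and symmetric-grid linear spectra reproduce their center
value.  Two uniform presets ship (10 nm 400–2500; 7 nm 400–2346); neither
claims to be the true CHIME grid, which is unpublished.  Exclusion windows
(535–550, 755–780, 810–855, 885–970, 1015–1050, 1080–1165, 1225–1285,
1330–1490, 1685–1700, 1725–1750, 1780–1960, 1990–2030 nm) remove bands by
center membership; the kept-band index is recorded in metadata and
mapping-time alignment is strictly metadata-driven (a cube lacking a
required band is a hard error, never a nearest-wavelength guess).

## Gaussian process regression

Zero-mean GP prior after target centering; features are z-scored with
training statistics (stored, so predictions return in original units).
The ARD Rational Quadratic kernel adds per-feature lengthscales σ_m² to
the usual (σ_f², α) pair; α → ∞ recovers the squared exponential.
Hyperparameters maximize the log marginal likelihood in log-parameter
space (L-BFGS-B, analytic gradients, 3 restarts by default, box bounds
±30 in log space to keep exponentials finite).  Initialization: unit
lengthscales on z-scored features, σ_f² = var(y), α = 1,
σ_n² = 0.01·var(y).  Cholesky factorizations fall back on a jitter ladder
(0, 10⁻¹⁰, 10⁻⁸, 10⁻⁶ × σ_f²); exhaustion raises a numerical error.
Line-search stalls on flat evidence surfaces are accepted when they leave
a finite optimum; a genuine failure logs a warning and returns the best
candidate.

Band relevance is `r_m = 100(1 − σ_m²/max_m σ_m²)` (the feature with the
largest lengthscale scores 0); a sum-normalized variant
`100(1 − σ_m²/Σσ_m²)` is available via `normalize="sum"`.  The two differ
only in scaling; both decrease in σ_m².

## Active learning

Pool-based EBD with accept-if-improved: compress the pool to 20 principal
components (loop efficiency only — the returned library keeps all bands),
seed with a random 10%-sized set (default 200 of 2000), then repeatedly
propose the candidate maximizing the minimum squared Euclidean distance to
the training set, retrain, and keep it only if reference RMSE strictly
decreases.  Rejected candidates are discarded permanently (prevents
livelock); `max_rejections_per_step` optionally stops a rejection streak
early.  Stopping: 500 accepted samples by default, or pool exhaustion —
early convergence is reported, not an error (training sets of 383 + 26
arise this way).  Traits without reference data (FAPAR, FVC) bypass the
loop with a random subset (default 1000).

Full evidence re-optimization at every proposal would dominate runtime, so
hyperparameters are refit every `refit_every` acceptances (default 25) and
the exact weight vector is recomputed at fixed hyperparameters in between;
a refit that worsens the reference metric is rolled back so the learning
curve stays monotone by construction.  Setting `refit_every=1` recovers
the always-refit behavior.

## PCA and sequential backward band removal

PCA is a covariance eigendecomposition of mean-centered reflectance (bands
share units, so no per-band standardization), with a deterministic sign
convention (largest-magnitude loading positive).  Component count: the
smallest n whose cumulative variance ratio exceeds 99.95%, floored at 20
in fixed-20 mode so both strategies use equally many features.

SBBR fixes a seeded random 3-fold partition once per run (iterations stay
comparable row to row), fits an ARD GP per fold on the surviving bands,
records mean/SD/min/max of the held-out R², and removes the band with the
highest mean rank of σ_m² across folds (ties to the lowest band index).
Consecutive iterations warm-start from the previous fold hyperparameters
with the removed lengthscale dropped (a from-scratch refit per iteration
is available with `warm_start=False`).  The ranking is the reversed
removal order; the top-k equals the surviving set of the k-band iteration.

## Evaluation statistics

`NRMSE = 100·RMSE/range(obs)`, `RRMSE = 100·RMSE/mean(obs)` (the
conventional reading of "relative RMSE").  R² defaults to the squared
Pearson correlation — validation tables in this field routinely pair
substantial errors with nonzero R², which is inconsistent with a
1:1-line coefficient of determination; that variant is available as
`r2_definition="deviation"`.  Map estimates are not clipped to physical
ranges (out-of-range values diagnose extrapolation); an optional clamp
exists but defaults off.

## Problem sizes in the test suite

The shipped suites run at desk scale as the package's own benchmark
conditions: collinearity on a 2000-sample pool at the 10 nm grid; AL
efficacy with pools of 2000, references of 200, budget 300, five paired
seeds; SBBR planted-band recovery at 120 samples × 40 bands × 10 seeds;
end-to-end mapping on a 50×50 scene with 600-sample pools on a 40 nm demo
grid.  On those conditions the FVC maps reach R² ≥ 0.99 against truth.
LAI tops out near R² ≈ 0.75–0.87 depending on sampling: the gap fraction
`exp(−k·LAI)` is nearly flat beyond LAI ≈ 4, so high-LAI spectra are
almost indistinguishable while leaf-angle and geometry variation still
perturb them — an informational ceiling intrinsic to Beer–Lambert
canopies, matching the well-known saturation of optical LAI retrieval.
The end-to-end quality bar in the tests is therefore R² ≥ 0.90 for FVC
and R² ≥ 0.65 for LAI.

## Known limitations

- The surrogate is not radiometrically faithful; absolute trait accuracies
  on real data are outside what the synthetic experiments can certify.
- BSM latitude/longitude are sampled but spectrally inert.
- The exact instrument grid and SRF shapes of CHIME are unpublished; all
  grids are configurable and the presets are declared stand-ins.
- Heteroscedastic noise, sparse GP approximations, and uncertainty-driven
  AL variants are out of scope.
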