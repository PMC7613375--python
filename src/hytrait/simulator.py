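"""Surrogate canopy radiative-transfer simulator for training-library generation.

Hybrid trait retrieval trains a regressor on simulated (spectrum, trait)
pairs.  Physically rigorous simulators (PROSPECT/SAIL/SCOPE) couple leaf
biochemistry, canopy structure, soil and sun-sensor geometry into top-of-
canopy reflectance.  This module implements a deliberately lightweight
surrogate with the same statistical structure — trait-driven Beer-Lambert
absorption features, gap-fraction mixing of vegetation and soil, weak
geometric modulation, strong inter-band collinearity — without claiming
radiometric fidelity.  Its outputs drive every downstream stage: active
learning, dimensionality reduction, Gaussian-process training and mapping.

The sampling scheme for the model inputs follows the standard crop-trait
parameterization: truncated Gaussians for the leaf biochemistry variables
(chlorophyll, water, dry matter, structure), uniform distributions for
carotenoids, LAI, leaf inclination, soil scaling and the sun-sensor angles,
and truncated Gaussians for the soil (BSM-style) variables.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, ValidationError
from .library import SpectralLibrary, TRAIT_NAMES
from .spectral import BandGrid

__all__ = [
    "DistributionSpec",
    "TraitSample",
    "TABLE_DISTRIBUTIONS",
    "sample_inputs",
    "simulate_leaf",
    "simulate_canopy",
    "derive_traits",
    "generate_library",
    "generate_nonvegetated",
    "generate_synthetic_cube",
]


# ---------------------------------------------------------------------------
# Input distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """Marginal distribution of one simulator input variable."""

    name: str
    kind: str  # "uniform" | "truncated-gaussian" | "fixed"
    min: float
    max: float
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self):
        if self.min > self.max:
            raise ValidationError(f"{self.name}: min {self.min} > max {self.max}")
        if self.kind not in ("uniform", "truncated-gaussian", "fixed"):
            raise ValidationError(f"{self.name}: unknown distribution kind {self.kind!r}")
        if self.kind == "truncated-gaussian":
            if self.mean is None or self.sd is None:
                raise ValidationError(f"{self.name}: truncated-gaussian needs mean and sd")
            if self.sd <= 0:
                raise ValidationError(f"{self.name}: sd must be positive")
        if self.kind == "fixed" and self.min != self.max:
            raise ValidationError(f"{self.name}: fixed distribution requires min == max")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.min)
        if self.kind == "uniform":
            return rng.uniform(self.min, self.max, n)
        # Truncated Gaussian by rejection inside [min, max]: avoids the
        # boundary atoms that clipping would create.
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, max(n - filled, 16) * 2)
            ok = draw[(draw >= self.min) & (draw <= self.max)]
            take = min(ok.size, n - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
        return out


def _tg(name, mean, sd, lo, hi):
    return DistributionSpec(name, "truncated-gaussian", lo, hi, mean, sd)


def _u(name, lo, hi):
    return DistributionSpec(name, "uniform", lo, hi)


#: Default input parameterization of the training library (leaf, canopy,
#: geometry and soil variables with their ranges and distributions).
TABLE_DISTRIBUTIONS: tuple[DistributionSpec, ...] = (
    _tg("N", 1.5, 0.5, 1.0, 2.7),          # leaf structure, unitless
    _tg("Cab", 45.0, 35.0, 0.0, 80.0),     # chlorophyll, ug/cm^2
    _tg("Cm", 0.0075, 0.005, 0.002, 0.02), # dry matter, g/cm^2
    _tg("Cw", 0.015, 0.0075, 0.005, 0.035),  # water, g/cm^2
    _u("Cxc", 0.0, 20.0),                  # carotenoids, ug/cm^2
    _u("LAI", 0.1, 8.0),                   # leaf area index, m^2/m^2
    _u("LIDF", -1.0, 1.0),                 # leaf inclination parameter
    _u("alpha_soil", 0.0, 1.0),            # soil scaling factor
    _u("SZA", 0.0, 80.0),                  # sun zenith, deg
    _u("OZA", 0.0, 25.0),                  # observer zenith, deg
    _u("RAA", 0.0, 180.0),                 # relative azimuth, deg
    _tg("SMC", 25.0, 12.5, 5.0, 55.0),     # soil moisture, %
    _tg("B_soil", 0.5, 0.25, 0.0, 0.9),    # soil brightness
    _tg("BSM_lat", 25.0, 12.5, 20.0, 40.0),
    _tg("BSM_lon", 50.0, 10.0, 45.0, 65.0),
)

INPUT_NAMES = tuple(s.name for s in TABLE_DISTRIBUTIONS)


@dataclass
class TraitSample:
    """One draw of simulator inputs plus the derived retrieval targets."""

    N: float
    Cab: float
    Cm: float
    Cw: float
    Cxc: float
    LAI: float
    LIDF: float
    alpha_soil: float
    SZA: float
    OZA: float
    RAA: float
    SMC: float
    B_soil: float
    BSM_lat: float
    BSM_lon: float
    # Derived targets (filled by derive_traits / generate_library)
    SLA: float | None = None
    CCC: float | None = None
    CWC: float | None = None
    FVC: float | None = None
    FAPAR: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def load_distribution_config(path) -> list[DistributionSpec]:
    """Load per-variable distribution specs from a YAML file.

    Schema: a list of mappings with keys ``name``, ``kind`` (uniform /
    truncated-gaussian / fixed), ``min``, ``max`` and, for truncated
    Gaussians, ``mean`` and ``sd``.  Variables not listed fall back to the
    package defaults.
    """
    import yaml

    entries = yaml.safe_load(Path(path).read_text())
    if not isinstance(entries, list):
        raise ConfigurationError("distribution config must be a YAML list")
    overrides = {}
    for e in entries:
        try:
            overrides[e["name"]] = DistributionSpec(
                name=e["name"], kind=e["kind"], min=float(e["min"]),
                max=float(e["max"]),
                mean=float(e["mean"]) if "mean" in e else None,
                sd=float(e["sd"]) if "sd" in e else None,
            )
        except KeyError as exc:
            raise ConfigurationError(f"distribution entry missing key {exc}") from exc
    return [overrides.get(s.name, s) for s in TABLE_DISTRIBUTIONS]


def sample_inputs(specs: Sequence[DistributionSpec], n: int, seed: int) -> list[TraitSample]:
    """Draw ``n`` reproducible input samples from the per-variable specs."""
    frame = sample_inputs_frame(specs, n, np.random.default_rng(seed))
    return [TraitSample(**{k: row[k] for k in INPUT_NAMES}) for _, row in frame.iterrows()]


def sample_inputs_frame(specs: Sequence[DistributionSpec], n: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized sampling into a DataFrame with one column per variable."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    by_name = {s.name: s for s in specs}
    missing = [v for v in INPUT_NAMES if v not in by_name]
    if missing:
        raise ConfigurationError(f"missing distribution spec(s) for: {missing}")
    return pd.DataFrame({name: by_name[name].draw(n, rng) for name in INPUT_NAMES})


# ---------------------------------------------------------------------------
# Optical surrogate
# ---------------------------------------------------------------------------

def _gauss_sum(wl, peaks):
    """Sum of Gaussians: peaks = [(center_nm, width_nm, amplitude), ...]."""
    out = np.zeros_like(wl, dtype=float)
    for c, w, a in peaks:
        out += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return out


@dataclass
class OpticalConstants:
    """Specific absorption templates and scattering/mixing constants.

    Absorption coefficients are sums of Gaussians centered on the known
    pigment / water / dry-matter features; amplitudes carry the units that
    make content x coefficient dimensionless (cm^2/ug for pigments,
    cm^2/g for water and dry matter).
    """

    k_ab_peaks: tuple = ((430, 30, 0.06), (660, 25, 0.04))
    k_xc_peaks: tuple = ((470, 30, 0.05),)
    k_w_peaks: tuple = ((970, 40, 5.0), (1200, 40, 10.0), (1450, 60, 60.0), (1940, 70, 90.0))
    k_m_peaks: tuple = ((1730, 60, 8.0), (2100, 80, 12.0), (2300, 60, 10.0))
    rho0: float = 0.02          # baseline leaf reflectance
    s0: float = 0.46            # scattering at N = 1.5 (NIR plateau ~0.48)
    s1: float = 0.05            # scattering sensitivity to leaf structure
    q_multi: float = 0.8        # multiple-scattering gain in the canopy
    kext0: float = 0.5          # nadir extinction at spherical leaf angles
    kext_lidf: float = 0.3      # extinction sensitivity to leaf inclination
    soil_r0_start: float = 0.10  # dry bright soil at 400 nm
    soil_r0_stop: float = 0.35   # dry bright soil at 2400 nm
    soil_moisture_gain: float = 0.7

    def k_ab(self, wl):
        return _gauss_sum(wl, self.k_ab_peaks)

    def k_xc(self, wl):
        return _gauss_sum(wl, self.k_xc_peaks)

    def k_w(self, wl):
        return _gauss_sum(wl, self.k_w_peaks)

    def k_m(self, wl):
        return _gauss_sum(wl, self.k_m_peaks)

    def soil_baseline(self, wl):
        t = np.clip((np.asarray(wl, float) - 400.0) / 2000.0, 0.0, 1.0)
        return self.soil_r0_start + (self.soil_r0_stop - self.soil_r0_start) * t

    def water_shape(self, wl):
        kw = self.k_w(wl)
        return kw / self.k_w(np.array([1940.0]))[0]


DEFAULT_OPTICS = OpticalConstants()


def _leaf_arrays(params: pd.DataFrame, wl: np.ndarray, optics: OpticalConstants):
    """Vectorized leaf optics: absorptance A and reflectance rho_leaf.

    a(lambda) = (Cab k_ab + Cxc k_xc + Cw k_w + Cm k_m) / N  (Beer-Lambert
    optical depth per unit structure), A = 1 - exp(-a), and
    rho_leaf = rho0 + s_N (1 - A) with s_N = s0 + s1 (N - 1.5).
    """
    for col in ("Cab", "Cxc", "Cw", "Cm"):
        if np.any(params[col].to_numpy() < 0):
            raise ValidationError(f"negative constituent content in column {col}")
    cab = params["Cab"].to_numpy()[:, None]
    cxc = params["Cxc"].to_numpy()[:, None]
    cw = params["Cw"].to_numpy()[:, None]
    cm = params["Cm"].to_numpy()[:, None]
    nstr = params["N"].to_numpy()[:, None]
    a = (cab * optics.k_ab(wl) + cxc * optics.k_xc(wl)
         + cw * optics.k_w(wl) + cm * optics.k_m(wl)) / nstr
    absorptance = 1.0 - np.exp(-a)
    s_n = optics.s0 + optics.s1 * (nstr - 1.5)
    rho_leaf = optics.rho0 + s_n * (1.0 - absorptance)
    return rho_leaf, absorptance


def _soil_array(params: pd.DataFrame, wl: np.ndarray, optics: OpticalConstants):
    """Soil reflectance surrogate: brightness-scaled baseline darkened by
    moisture through the water-absorption shape.  The BSM latitude/longitude
    inputs are sampled for completeness but spectrally inert (documented
    limitation)."""
    alpha = params["alpha_soil"].to_numpy()[:, None]
    bright = params["B_soil"].to_numpy()[:, None]
    smc = params["SMC"].to_numpy()[:, None]
    return alpha * bright * optics.soil_baseline(wl) * (
        1.0 - optics.soil_moisture_gain * (smc / 100.0) * optics.water_shape(wl)
    )


def _canopy_arrays(params: pd.DataFrame, rho_leaf, absorptance, r_soil,
                   optics: OpticalConstants):
    """Gap-fraction mixing of leaf and soil with weak geometric modulation.

    P = exp(-k_ext LAI) is the nadir gap fraction (Beer-Lambert canopy
    transmission); the (1 + q (1 - A)) factor is a declared stand-in for
    multiple scattering in weakly absorbing regions.
    """
    lai = params["LAI"].to_numpy()[:, None]
    if np.any(lai < 0):
        raise ValidationError("LAI must be non-negative")
    lidf = params["LIDF"].to_numpy()[:, None]
    kext = optics.kext0 * (1.0 + optics.kext_lidf * lidf)
    gap = np.exp(-kext * lai)
    sza = np.deg2rad(params["SZA"].to_numpy()[:, None])
    oza = np.deg2rad(params["OZA"].to_numpy()[:, None])
    raa = np.deg2rad(params["RAA"].to_numpy()[:, None])
    g_geo = 1.0 + 0.05 * (np.cos(oza) - 1.0) + 0.02 * np.cos(raa) * np.sin(sza) * np.sin(oza)
    refl = g_geo * ((1.0 - gap) * rho_leaf * (1.0 + optics.q_multi * (1.0 - absorptance))
                    + gap * r_soil)
    return np.clip(refl, 0.0, 1.0), gap


def _derive_frame(params: pd.DataFrame, absorptance, gap, wl) -> pd.DataFrame:
    """Derived retrieval targets from inputs + leaf absorptance + gap fraction.

    SLA = 1/Cm (cm^2/g); CCC = LAI Cab 1e-2 (g/m^2); CWC = LAI Cw 1e4 (g/m^2);
    FVC = 1 - P; FAPAR = (1 - P) x mean leaf absorptance over 400-700 nm.
    """
    cm = params["Cm"].to_numpy()
    if np.any(cm <= 0):
        raise ValidationError("Cm must be positive to define SLA = 1/Cm")
    par = (wl >= 400) & (wl <= 700)
    if not np.any(par):
        raise ValidationError("wavelength grid has no 400-700 nm support for FAPAR")
    gap1 = np.asarray(gap).reshape(len(params))
    mean_a = np.asarray(absorptance)[:, par].mean(axis=1)
    return pd.DataFrame({
        "SLA": 1.0 / cm,
        "LAI": params["LAI"].to_numpy(),
        "CCC": params["LAI"].to_numpy() * params["Cab"].to_numpy() * 1e-2,
        "CWC": params["LAI"].to_numpy() * params["Cw"].to_numpy() * 1e4,
        "FAPAR": (1.0 - gap1) * mean_a,
        "FVC": 1.0 - gap1,
    })


# -- per-sample wrappers (the scalar public surface) -------------------------

def _frame_of(sample: TraitSample) -> pd.DataFrame:
    return pd.DataFrame([{k: getattr(sample, k) for k in INPUT_NAMES}])


def simulate_leaf(sample: TraitSample, wavelengths,
                  optics: OpticalConstants = DEFAULT_OPTICS):
    """Leaf reflectance and absorptance spectra for one input sample."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.min() < 400 or wl.max() > 2500:
        raise ValidationError("wavelengths must lie within 400-2500 nm")
    rho, ab = _leaf_arrays(_frame_of(sample), wl, optics)
    return rho[0], ab[0]


def simulate_canopy(sample: TraitSample, leaf_pair, soil_spectrum,
                    optics: OpticalConstants = DEFAULT_OPTICS):
    """Top-of-canopy reflectance from a leaf (rho, A) pair and a soil spectrum."""
    rho_leaf, absorptance = leaf_pair
    rho_leaf = np.atleast_2d(np.asarray(rho_leaf, float))
    absorptance = np.atleast_2d(np.asarray(absorptance, float))
    r_soil = np.atleast_2d(np.asarray(soil_spectrum, float))
    if rho_leaf.shape != r_soil.shape:
        raise ValidationError("leaf and soil spectra must share one wavelength grid")
    refl, gap = _canopy_arrays(_frame_of(sample), rho_leaf, absorptance, r_soil, optics)
    return refl[0], float(gap[0, 0])


def derive_traits(sample: TraitSample, absorptance, gap: float, wavelengths) -> TraitSample:
    """Fill the derived targets of a sample in place (returned for chaining)."""
    if not 0.0 <= gap <= 1.0:
        raise ValidationError("gap fraction P must be in [0, 1]")
    frame = _derive_frame(_frame_of(sample), np.atleast_2d(absorptance),
                          np.array([gap]), np.asarray(wavelengths, float))
    for k in ("SLA", "CCC", "CWC", "FVC", "FAPAR"):
        setattr(sample, k, float(frame[k].iloc[0]))
    return sample


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _simulate_frame(params: pd.DataFrame, wl: np.ndarray,
                    optics: OpticalConstants):
    """End-to-end vectorized simulation: inputs -> (reflectance, trait frame)."""
    rho_leaf, absorptance = _leaf_arrays(params, wl, optics)
    r_soil = _soil_array(params, wl, optics)
    refl, gap = _canopy_arrays(params, rho_leaf, absorptance, r_soil, optics)
    traits = _derive_frame(params, absorptance, gap[:, 0], wl)
    return refl, traits


def generate_library(specs: Sequence[DistributionSpec] = TABLE_DISTRIBUTIONS,
                     n: int = 2000,
                     grid: BandGrid | None = None,
                     seed: int = 0,
                     optics: OpticalConstants = DEFAULT_OPTICS) -> SpectralLibrary:
    """Generate a trait-labeled canopy reflectance library.

    The default pool size of 2000 matches the standard training-database
    size for hybrid retrieval before active-learning reduction.
    """
    from .spectral import build_band_grid

    if grid is None:
        grid = build_band_grid(400, 2500, 10, 10, "chime10")
    rng = np.random.default_rng(seed)
    params = sample_inputs_frame(specs, n, rng)
    refl, traits = _simulate_frame(params, grid.centers, optics)
    table = pd.concat([traits, params.drop(columns=["LAI"])], axis=1)
    table["provenance"] = "vegetated"
    return SpectralLibrary(
        wavelengths=grid.centers.copy(),
        reflectance=refl,
        traits=table,
        metadata={"seed": int(seed), "generator": "hytrait-surrogate-1",
                  "grid_id": grid.grid_id, "n": int(n)},
    )


# ---------------------------------------------------------------------------
# Non-vegetated augmentation spectra
# ---------------------------------------------------------------------------

#: Default mix of non-vegetated surface archetypes.
NONVEG_CLASS_PROBS = {"bright_soil": 0.3, "dark_soil": 0.2, "water": 0.3, "man_made": 0.2}


def _archetype_spectrum(cls: str, wl: np.ndarray,
                        optics: OpticalConstants = DEFAULT_OPTICS) -> np.ndarray:
    """Deterministic archetype templates for non-vegetated surfaces."""
    if cls == "bright_soil":
        return 1.6 * optics.soil_baseline(wl) * (1.0 - 0.15 * optics.water_shape(wl))
    if cls == "dark_soil":
        return 0.5 * optics.soil_baseline(wl) * (1.0 - 0.35 * optics.water_shape(wl))
    if cls == "water":
        # Low overall, decaying beyond the red edge: strong liquid-water
        # absorption leaves SWIR reflectance near zero.
        base = 0.02 + 0.06 * np.exp(-np.clip(wl - 550.0, 0.0, None) / 180.0)
        return base
    if cls == "man_made":
        return np.full_like(wl, 0.22, dtype=float)
    raise ConfigurationError(f"unknown non-vegetated archetype {cls!r}")


def generate_nonvegetated(n: int = 26,
                          grid: BandGrid | None = None,
                          seed: int = 0,
                          jitter: float = 0.15,
                          class_probs: dict | None = None,
                          optics: OpticalConstants = DEFAULT_OPTICS) -> SpectralLibrary:
    """Generate non-vegetated augmentation spectra with all trait targets 0.

    Adding zero-labeled soil/water/man-made spectra to a training set teaches
    the regressor to return near-zero trait values on non-vegetated pixels;
    the conventional augmentation size is 26 spectra.
    """
    from .spectral import build_band_grid

    if n < 1:
        raise ValidationError("n must be >= 1")
    if grid is None:
        grid = build_band_grid(400, 2500, 10, 10, "chime10")
    probs = dict(NONVEG_CLASS_PROBS if class_probs is None else class_probs)
    classes = list(probs)
    p = np.asarray([probs[c] for c in classes], float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    labels = rng.choice(classes, size=n, p=p)
    wl = grid.centers
    spectra = np.empty((n, wl.size))
    for i, cls in enumerate(labels):
        base = _archetype_spectrum(cls, wl, optics)
        if jitter > 0:
            level = 1.0 + jitter * rng.standard_normal()
            smooth = ndimage.gaussian_filter1d(rng.standard_normal(wl.size), 8.0)
            shape = 1.0 + 0.5 * jitter * smooth / max(np.abs(smooth).max(), 1e-12)
            spectra[i] = base * max(level, 0.2) * shape
        else:
            spectra[i] = base
    spectra = np.clip(spectra, 0.0, 1.0)
    traits = pd.DataFrame({t: np.zeros(n) for t in TRAIT_NAMES})
    traits["provenance"] = "non-vegetated"
    traits["surface_class"] = labels
    return SpectralLibrary(
        wavelengths=wl.copy(),
        reflectance=spectra,
        traits=traits,
        metadata={"seed": int(seed), "generator": "hytrait-nonveg-1",
                  "grid_id": grid.grid_id},
    )


# ---------------------------------------------------------------------------
# Synthetic scenes
# ---------------------------------------------------------------------------

def _smooth_field(shape, rng, sigma=8.0):
    """Low-frequency random surface in (0, 1): smoothed white noise mapped
    through its empirical normal CDF."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    if sd < 1e-12:
        return np.full(shape, 0.5)
    from scipy.special import ndtr

    return ndtr(f / sd)


def generate_synthetic_cube(rows: int, cols: int,
                            grid: BandGrid | None = None,
                            seed: int = 0,
                            nonveg_fraction: float = 0.2,
                            fixed_sample: TraitSample | None = None,
                            class_probs: dict | None = None,
                            fine_step: float | None = None,
                            optics: OpticalConstants = DEFAULT_OPTICS):
    """Synthetic hyperspectral scene with per-pixel truth trait maps.

    Trait fields vary smoothly in space (low-frequency random surfaces mapped
    into the simulator's input ranges); a spatially coherent subset of pixels
    is assigned non-vegetated archetypes with zero truth.  Stands in for a
    real satellite scene in end-to-end tests.

    With ``fine_step`` set, spectra are simulated on a fine internal grid and
    resampled to ``grid`` with Gaussian SRFs — the same observation path as
    :func:`hytrait.workflow.build_pool`, so training libraries and scenes see
    identically convolved bands.

    Returns ``(cube, truth, class_map)``: cube (rows, cols, bands); truth a
    dict of (rows, cols) arrays per trait; class_map an object array with
    "vegetated" or archetype labels.
    """
    from .spectral import build_band_grid, gaussian_resample

    if rows < 1 or cols < 1:
        raise ValidationError("rows and cols must be >= 1")
    if grid is None:
        grid = build_band_grid(400, 2500, 10, 10, "chime10")
    rng = np.random.default_rng(seed)
    if fine_step is not None:
        sim_grid = build_band_grid(400, 2500, fine_step, fine_step)
        wl = sim_grid.centers
    else:
        wl = grid.centers
    npx = rows * cols

    if fixed_sample is not None:
        params = pd.concat([_frame_of(fixed_sample)] * npx, ignore_index=True)
        nonveg_fraction = 0.0
    else:
        by_name = {s.name: s for s in TABLE_DISTRIBUTIONS}
        cols_d = {}
        for name in INPUT_NAMES:
            spec = by_name[name]
            u = _smooth_field((rows, cols), rng, sigma=max(min(rows, cols) / 6.0, 2.0))
            if spec.kind == "fixed":
                vals = np.full((rows, cols), spec.min)
            else:
                # Map the smooth uniform field through the marginal: linear
                # for uniforms; for truncated Gaussians use the quantile of
                # the underlying normal clipped to the support.
                if spec.kind == "uniform":
                    vals = spec.min + (spec.max - spec.min) * u
                else:
                    from scipy.stats import truncnorm

                    a = (spec.min - spec.mean) / spec.sd
                    b = (spec.max - spec.mean) / spec.sd
                    vals = truncnorm.ppf(np.clip(u, 1e-9, 1 - 1e-9), a, b,
                                         loc=spec.mean, scale=spec.sd)
            cols_d[name] = vals.ravel()
        params = pd.DataFrame(cols_d)

    refl, traits = _simulate_frame(params, wl, optics)
    class_map = np.full(npx, "vegetated", dtype=object)

    if nonveg_fraction > 0:
        probs = dict(NONVEG_CLASS_PROBS if class_probs is None else class_probs)
        cls_names = list(probs)
        p = np.asarray([probs[c] for c in cls_names], float)
        p = p / p.sum()
        occupancy = _smooth_field((rows, cols), rng,
                                  sigma=max(min(rows, cols) / 8.0, 2.0)).ravel()
        nonveg_idx = np.flatnonzero(occupancy < nonveg_fraction)
        if nonveg_idx.size:
            labels = rng.choice(cls_names, size=nonveg_idx.size, p=p)
            for i, cls in zip(nonveg_idx, labels):
                base = _archetype_spectrum(cls, wl, optics)
                level = max(1.0 + 0.1 * rng.standard_normal(), 0.3)
                refl[i] = np.clip(base * level, 0.0, 1.0)
                class_map[i] = cls
            traits.iloc[nonveg_idx] = 0.0
    elif class_probs is not None and fixed_sample is None:
        pass

    if fine_step is not None:
        refl = gaussian_resample(wl, refl, grid)
    cube = refl.reshape(rows, cols, grid.centers.size)
    truth = {t: traits[t].to_numpy().reshape(rows, cols) for t in TRAIT_NAMES}
    return cube, truth, class_map.reshape(rows, cols)


def generate_nonveg_cube(rows: int, cols: int, cls: str = "water",
                         grid: BandGrid | None = None, seed: int = 0,
                         optics: OpticalConstants = DEFAULT_OPTICS):
    """Scene made entirely of one non-vegetated archetype (truth all zero)."""
    from .spectral import build_band_grid

    if grid is None:
        grid = build_band_grid(400, 2500, 10, 10, "chime10")
    rng = np.random.default_rng(seed)
    wl = grid.centers
    base = _archetype_spectrum(cls, wl, optics)
    levels = np.clip(1.0 + 0.1 * rng.standard_normal(rows * cols), 0.3, None)
    cube = np.clip(levels[:, None] * base, 0.0, 1.0).reshape(rows, cols, wl.size)
    truth = {t: np.zeros((rows, cols)) for t in TRAIT_NAMES}
    class_map = np.full((rows, cols), cls, dtype=object)
    return cube, truth, class_map
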