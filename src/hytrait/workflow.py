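"""End-to-end orchestration of the two retrieval strategies.

``run_strategy`` wires the stages together for one trait: training pool ->
active-learning reduction (or a random-subset bypass for traits without
reference data) -> zero-labeled non-vegetated augmentation -> spectral
reduction (20 principal components, the 20 best-ranked bands, or all bands)
-> GP training -> validation.  ``map_traits`` applies a trained bundle to a
hyperspectral cube, producing per-pixel estimates with predictive SD and
relative uncertainty (CV%).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gpr
from .active_learning import ALConfig, al_run, augment_zero_spectra, random_bypass
from .dimred import (PCAModel, pca_fit, pca_transform, sbbr_run,
                     select_best_band_indices)
from .errors import ValidationError
from .evaluation import FitStats, goodness_of_fit
from .library import SpectralLibrary
from .simulator import generate_library, generate_nonvegetated
from .spectral import (BandGrid, DEFAULT_EXCLUSION_WINDOWS, ExclusionWindows,
                       apply_exclusion_windows, build_band_grid, resample_library)

__all__ = ["StrategyConfig", "TraitMap", "ModelBundle", "build_pool",
           "run_strategy", "map_traits"]

log = logging.getLogger(__name__)

#: Traits for which no in-situ reference is normally available; trained on a
#: random pool subset instead of the AL loop.
BYPASS_TRAITS = ("FAPAR", "FVC")


@dataclass
class StrategyConfig:
    """Configuration of one trait-specific retrieval strategy."""

    variable: str
    mode: str = "PCA"              # "PCA" | "BR" | "ALL_BANDS"
    n_features: int = 20
    al: ALConfig | None = None     # None -> defaults (or bypass for FAPAR/FVC)
    bypass_n: int = 1000
    nonveg_n: int = 26
    seed: int = 0
    sbbr_folds: int = 3
    eval_n: int = 500              # simulated test-set size when no reference

    def __post_init__(self):
        if self.variable not in ("SLA", "LAI", "CCC", "CWC", "FAPAR", "FVC"):
            raise ValidationError(f"unknown trait {self.variable!r}")
        if self.mode not in ("PCA", "BR", "ALL_BANDS"):
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass
class ModelBundle:
    """Everything needed to apply a trained strategy to new spectra."""

    variable: str
    mode: str
    model: gpr.GPRModel
    wavelengths: np.ndarray             # bands the bundle's transform expects
    grid_id: str
    kept_band_index: list | None        # indices into the pre-exclusion grid
    pca: PCAModel | None = None         # PCA mode
    band_index: np.ndarray | None = None  # BR mode: indices into wavelengths
    stats: FitStats | None = None
    training_rows: int = 0
    train_time_s: float = 0.0

    @property
    def n_features(self) -> int:
        return self.model.n_features

    def transform(self, spectra) -> np.ndarray:
        """Map full-band spectra to the bundle's model feature space."""
        X = np.atleast_2d(np.asarray(spectra, float))
        if X.shape[1] != self.wavelengths.size:
            raise ValidationError(
                f"spectra have {X.shape[1]} bands; bundle expects "
                f"{self.wavelengths.size} (grid {self.grid_id})"
            )
        if self.mode == "PCA":
            return pca_transform(self.pca, X, self.n_features)
        if self.mode == "BR":
            return X[:, self.band_index]
        return X


@dataclass
class TraitMap:
    """Per-pixel trait estimate grid with uncertainty layers."""

    estimate: np.ndarray
    sd: np.ndarray
    cv_percent: np.ndarray
    mask: np.ndarray                   # True where valid
    variable: str
    provenance: dict = field(default_factory=dict)


def build_pool(n: int = 2000, grid: BandGrid | None = None,
               windows: ExclusionWindows | None = DEFAULT_EXCLUSION_WINDOWS,
               seed: int = 0, fine_step: float = 1.0) -> SpectralLibrary:
    """Simulate a training pool the way a scene would be observed.

    Spectra are simulated on a fine internal grid (``fine_step`` nm), then
    resampled to the instrument band grid with Gaussian SRFs, then reduced
    by the exclusion windows.
    """
    if grid is None:
        grid = build_band_grid(400, 2500, 10, 10, "chime10")
    fine = build_band_grid(400, 2500, fine_step, fine_step, f"fine_{fine_step:g}nm")
    lib = generate_library(n=n, grid=fine, seed=seed)
    lib = resample_library(lib, grid)
    if windows is not None:
        lib = apply_exclusion_windows(lib, windows)
    return lib


def run_strategy(config: StrategyConfig, pool: SpectralLibrary,
                 reference: SpectralLibrary | None = None,
                 nonveg: SpectralLibrary | None = None) -> ModelBundle:
    """Train one trait-specific retrieval model end to end.

    ``pool`` (and ``reference``, if given) must already be on the final band
    grid.  When ``nonveg`` is None, ``config.nonveg_n`` archetype spectra are
    generated on the pool's grid.
    """
    t0 = time.perf_counter()
    var = config.variable
    use_bypass = reference is None or var in BYPASS_TRAITS

    # -- sample reduction ---------------------------------------------------
    if use_bypass:
        log.info("[%s] random bypass: %d samples", var, config.bypass_n)
        train_lib = random_bypass(pool, min(config.bypass_n, pool.n_samples),
                                  seed=config.seed)
    else:
        al_cfg = config.al or ALConfig(seed=config.seed)
        log.info("[%s] EBD active learning to %d samples", var, al_cfg.stop_size)
        train_lib = al_run(pool, reference, var, al_cfg).library

    # -- zero-labeled augmentation ------------------------------------------
    if nonveg is None and config.nonveg_n > 0:
        nonveg = generate_nonvegetated(
            config.nonveg_n,
            grid=BandGrid(pool.wavelengths, np.full(pool.n_bands, 10.0),
                          pool.metadata.get("grid_id", "custom")),
            seed=config.seed + 1,
        )
    train_lib = augment_zero_spectra(train_lib, nonveg)

    # -- spectral reduction + GP fit ----------------------------------------
    pca = band_index = None
    if config.mode == "PCA":
        pca = pca_fit(train_lib.reflectance, n_components=config.n_features)
        X = pca_transform(pca, train_lib.reflectance)
    elif config.mode == "BR":
        sbbr = sbbr_run(train_lib, var, folds=config.sbbr_folds, seed=config.seed)
        band_index = select_best_band_indices(sbbr, config.n_features)
        X = train_lib.reflectance[:, band_index]
    else:
        X = train_lib.reflectance
    y = train_lib.targets(var)
    model = gpr.fit(X, y, restarts=2, seed=config.seed)
    train_time = time.perf_counter() - t0

    bundle = ModelBundle(
        variable=var, mode=config.mode, model=model,
        wavelengths=pool.wavelengths.copy(),
        grid_id=pool.metadata.get("grid_id", "custom"),
        kept_band_index=pool.metadata.get("kept_band_index"),
        pca=pca, band_index=band_index,
        training_rows=train_lib.n_samples, train_time_s=train_time,
    )

    # -- validation ----------------------------------------------------------
    if reference is not None:
        eval_lib = reference
    else:
        eval_lib = None
    if eval_lib is not None:
        pred = gpr.predict(model, bundle.transform(eval_lib.reflectance))
        bundle.stats = goodness_of_fit(eval_lib.targets(var), pred.mean)
    return bundle


def _align_cube(bundle: ModelBundle, cube, cube_wavelengths):
    """Strict band alignment: the cube must provide exactly the bundle's
    wavelengths (metadata-driven; no nearest-wavelength guessing)."""
    cube = np.asarray(cube, float)
    if cube.ndim != 3:
        raise ValidationError("cube must be (rows, cols, bands)")
    if cube_wavelengths is None:
        if cube.shape[2] != bundle.wavelengths.size:
            raise ValidationError(
                "cube carries no wavelengths and its band count does not "
                "match the bundle's grid"
            )
        return cube
    wl = np.asarray(cube_wavelengths, float)
    if wl.size == bundle.wavelengths.size and np.allclose(wl, bundle.wavelengths,
                                                          atol=1e-6):
        return cube
    # Exact subset selection by metadata, never nearest-neighbour.
    idx = []
    for w in bundle.wavelengths:
        j = np.flatnonzero(np.isclose(wl, w, atol=1e-6))
        if j.size == 0:
            raise ValidationError(
                f"cube lacks the {w:g} nm band required by the model bundle "
                f"(grid {bundle.grid_id}); resample/exclude the cube first"
            )
        idx.append(int(j[0]))
    return cube[..., idx]


def map_traits(bundle: ModelBundle, cube, cube_wavelengths=None,
               mask=None, clamp_range: tuple | None = None) -> TraitMap:
    """Apply a trained bundle pixel-wise to a hyperspectral cube.

    Estimates are *not* clipped to physical ranges by default: out-of-range
    values are a useful diagnostic of model extrapolation.  An optional
    ``clamp_range=(lo, hi)`` post-hoc clamp is available.
    """
    cube = _align_cube(bundle, cube, cube_wavelengths)
    rows, cols, _ = cube.shape
    flat = cube.reshape(rows * cols, -1)
    valid = np.all(np.isfinite(flat), axis=1)
    if mask is not None:
        valid &= np.asarray(mask, bool).ravel()
    if not np.any(valid):
        raise ValidationError("no valid pixels to map")
    est = np.full(rows * cols, np.nan)
    sd = np.full(rows * cols, np.nan)
    cv = np.full(rows * cols, np.nan)
    pred = gpr.predict(bundle.model, bundle.transform(flat[valid]))
    est[valid] = pred.mean
    sd[valid] = pred.sd
    cv[valid] = pred.cv_percent
    if clamp_range is not None:
        est[valid] = np.clip(est[valid], clamp_range[0], clamp_range[1])
    return TraitMap(
        estimate=est.reshape(rows, cols),
        sd=sd.reshape(rows, cols),
        cv_percent=cv.reshape(rows, cols),
        mask=valid.reshape(rows, cols),
        variable=bundle.variable,
        provenance={"mode": bundle.mode, "grid_id": bundle.grid_id,
                    "n_features": bundle.n_features,
                    "training_rows": bundle.training_rows},
    )


def write_manifest(path, argv, config: dict, seed: int | None = None) -> None:
    """Record an invocation: arguments, config hash, package version."""
    from . import __version__

    payload = {
        "argv": list(argv),
        "config": config,
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
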