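"""Spectral dimensionality reduction: PCA and sequential backward band removal.

Hyperspectral reflectance is massively collinear; two competing reductions
feed the GP regressor:

* **PCA** — eigendecomposition of the band covariance matrix; components are
  retained either by a cumulative explained-variance rule (default 99.95%)
  or as a fixed count (20 for a fair cross-strategy comparison).
* **SBBR** (sequential backward band removal) — a wrapper around the ARD GP:
  at each iteration a GP is trained per cross-validation fold on the
  surviving bands, the band with the largest fitted squared lengthscale
  (least relevant) by cross-fold rank consensus is removed, and the
  procedure repeats until one band remains.  The reversed removal order is
  the band ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gpr
from .errors import ValidationError
from .evaluation import goodness_of_fit
from .library import SpectralLibrary

__all__ = ["PCAModel", "SBBRResult", "pca_fit", "select_n_components",
           "pca_transform", "pca_inverse_transform", "sbbr_run", "select_best_bands"]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """PCA of a spectra matrix: loadings, eigenvalues, variance ratios."""

    mean: np.ndarray            # feature means (B,)
    components: np.ndarray      # orthonormal loadings, rows = components (K x B)
    eigenvalues: np.ndarray     # descending, all components
    explained_variance_ratio: np.ndarray
    n_components: int


def pca_fit(spectra, n_components: int | None = None) -> PCAModel:
    """Eigendecomposition of the feature covariance of mean-centered spectra.

    PCA on raw centered reflectance (bands share units, so no standardization).
    Sign convention: in each component the largest-magnitude loading element
    is positive, making the decomposition deterministic.
    """
    X = np.atleast_2d(np.asarray(spectra, float))
    n, b = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):  # deterministic sign
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    ratios = evals / total if total > 0 else np.zeros_like(evals)
    k = b if n_components is None else min(n_components, b)
    return PCAModel(mean=mean, components=evecs.T, eigenvalues=evals,
                    explained_variance_ratio=ratios, n_components=k)


def select_n_components(model: PCAModel, threshold: float = 0.9995,
                        cap: int | None = None) -> int:
    """Smallest component count whose cumulative variance ratio exceeds the
    threshold; with ``cap`` given, at least ``cap`` components are kept
    (fixed-count mode, e.g. always 20)."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    csum = np.cumsum(model.explained_variance_ratio)
    above = np.flatnonzero(csum > threshold)
    if above.size == 0:
        log.warning("variance threshold %.6f numerically unreachable; "
                    "keeping all %d components", threshold, csum.size)
        n = csum.size
    else:
        n = int(above[0]) + 1
    if cap is not None:
        n = min(max(n, cap), model.eigenvalues.size)
    return n


def pca_transform(model: PCAModel, spectra, n_components: int | None = None):
    """Project spectra onto the retained components (scores)."""
    X = np.atleast_2d(np.asarray(spectra, float))
    if X.shape[1] != model.mean.size:
        raise ValidationError(
            f"spectra have {X.shape[1]} bands, PCA was fitted on {model.mean.size}"
        )
    k = model.n_components if n_components is None else n_components
    return (X - model.mean) @ model.components[:k].T


def pca_inverse_transform(model: PCAModel, scores):
    """Map component scores back to (approximate) spectra."""
    Z = np.atleast_2d(np.asarray(scores, float))
    return Z @ model.components[: Z.shape[1]] + model.mean


# ---------------------------------------------------------------------------
# Sequential backward band removal
# ---------------------------------------------------------------------------

@dataclass
class SBBRResult:
    """Per-iteration survival table and the final band ranking."""

    table: pd.DataFrame          # columns: n_bands, r2, sd, min, max, wavelengths
    ranking: np.ndarray          # wavelengths, most relevant first
    ranking_index: np.ndarray    # indices into the original band list
    per_fold_rankings: list      # per-iteration per-fold relevance ranks
    iterations: list             # surviving band-index arrays per iteration


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded random partition into near-equal folds, fixed for the whole run."""
    labels = np.repeat(np.arange(folds), int(np.ceil(n / folds)))[:n]
    rng.shuffle(labels)
    return labels


def sbbr_run(library: SpectralLibrary, variable: str, folds: int = 3,
             seed: int = 0, warm_start: bool = True, restarts: int = 1,
             maxiter: int = 60, warm_maxiter: int = 25) -> SBBRResult:
    """Sequential backward band removal with k-fold cross-validation.

    Per iteration and per fold, a GP with ARD lengthscales is fitted on the
    surviving bands of the training folds and validated on the held-out fold
    (R^2 mean/SD/min/max recorded).  The band whose squared lengthscale has
    the highest mean rank across folds (i.e. the least relevant by
    cross-fold consensus) is removed; ties break to the lowest band index.
    Folds are fixed across iterations so the survival table is comparable
    row to row.  ``warm_start`` reuses each fold's hyperparameters from the
    previous iteration (dropping the removed lengthscale), which keeps the
    quadratic-in-bands sweep at desk scale; a from-scratch refit per
    iteration is available with ``warm_start=False``.
    """
    y = library.targets(variable)
    X = library.reflectance
    n, b = X.shape
    if n < folds:
        raise ValidationError(f"need at least {folds} samples for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    fold_of = _fold_assignment(n, folds, rng)

    surviving = np.arange(b)
    removal_order: list[int] = []
    rows = []
    per_fold_rankings = []
    iterations = []
    fold_models: list = [None] * folds

    while surviving.size >= 1:
        iterations.append(surviving.copy())
        fold_r2 = []
        fold_l2 = np.empty((folds, surviving.size))
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            init = None
            if warm_start and fold_models[f] is not None:
                init = fold_models[f]
            model = gpr.fit(
                X[tr][:, surviving], y[tr], init=init,
                restarts=1 if init is not None else restarts,
                seed=seed + f, maxiter=warm_maxiter if init is not None else maxiter,
            )
            fold_models[f] = model.theta
            pred = gpr.predict(model, X[te][:, surviving])
            fold_r2.append(goodness_of_fit(y[te], pred.mean).r2)
            fold_l2[f] = model.theta.lengthscales2
        fold_r2 = np.asarray(fold_r2)
        rows.append({
            "n_bands": int(surviving.size),
            "r2": float(fold_r2.mean()),
            "sd": float(fold_r2.std(ddof=1)) if folds > 1 else 0.0,
            "min": float(fold_r2.min()),
            "max": float(fold_r2.max()),
            "wavelengths": " ".join(f"{library.wavelengths[i]:g}" for i in surviving),
        })
        if surviving.size == 1:
            removal_order.append(int(surviving[0]))
            break
        # Rank lengthscales within each fold (largest l2 -> largest rank ->
        # least relevant); remove by highest mean rank across folds.
        ranks = np.argsort(np.argsort(fold_l2, axis=1), axis=1)  # 0..B-1 per fold
        per_fold_rankings.append(ranks)
        mean_rank = ranks.mean(axis=0)
        worst_local = int(np.argmax(mean_rank))  # first max -> lowest index tie-break
        removal_order.append(int(surviving[worst_local]))
        surviving = np.delete(surviving, worst_local)
        if warm_start:
            for f in range(folds):
                th = fold_models[f]
                fold_models[f] = gpr.GPRHyperparams(
                    signal_var=th.signal_var, alpha_mix=th.alpha_mix,
                    lengthscales2=np.delete(th.lengthscales2, worst_local),
                    noise_var=th.noise_var,
                )

    ranking_index = np.asarray(removal_order[::-1], dtype=int)
    return SBBRResult(
        table=pd.DataFrame(rows),
        ranking=library.wavelengths[ranking_index],
        ranking_index=ranking_index,
        per_fold_rankings=per_fold_rankings,
        iterations=iterations,
    )


def select_best_bands(result: SBBRResult, k: int = 20) -> np.ndarray:
    """Wavelengths of the k best bands, ascending.

    The top-k of the ranking equals the surviving band set at the iteration
    with k bands (the ranking is the reversed removal order).
    """
    b = result.ranking_index.size
    if k > b:
        raise ValidationError(f"k={k} exceeds the {b} ranked bands")
    return np.sort(result.ranking[:k])


def select_best_band_indices(result: SBBRResult, k: int = 20) -> np.ndarray:
    """Original band indices of the k best bands, ascending."""
    b = result.ranking_index.size
    if k > b:
        raise ValidationError(f"k={k} exceeds the {b} ranked bands")
    return np.sort(result.ranking_index[:k])
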