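"""Pool-based training-set optimization by Euclidean-distance diversity (EBD).

Simulated training pools are large and redundant.  EBD active learning
shrinks them: starting from a small random seed set, the candidate most
distant (squared Euclidean distance to its nearest training sample) is
proposed, the regressor retrained, and the candidate kept only if the error
on a reference set strictly decreases.  Rejected candidates are discarded
permanently.  The loop runs in a PCA-compressed feature space for speed but
the returned library keeps all spectral bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gpr
from .dimred import pca_fit, pca_transform
from .errors import ValidationError
from .evaluation import goodness_of_fit
from .library import SpectralLibrary

__all__ = ["ALConfig", "ALResult", "ebd_distance", "ebd_select", "al_run",
           "augment_zero_spectra", "random_bypass"]

log = logging.getLogger(__name__)


@dataclass
class ALConfig:
    """Active-learning loop configuration.

    Defaults follow the standard recipe: a random seed set of 200 samples
    (10% of a 2000-sample pool), a stopping criterion of 500 accepted
    samples, RMSE as the acceptance metric, and 20 principal components for
    in-loop spectral compression.
    """

    initial_size: int = 200
    stop_size: int = 500
    metric: str = "rmse"
    n_components: int = 20
    seed: int = 0
    max_rejections_per_step: int | None = None
    refit_every: int = 25      # full hyperparameter refit cadence (acceptances)
    gpr_restarts: int = 1
    gpr_maxiter: int = 60

    def validate(self, pool_size: int) -> None:
        if not (0 < self.initial_size < self.stop_size <= pool_size):
            raise ValidationError(
                f"need 0 < initial_size ({self.initial_size}) < stop_size "
                f"({self.stop_size}) <= pool size ({pool_size})"
            )


@dataclass
class ALResult:
    """Chronology of an active-learning run."""

    accepted_indices: list          # pool row indices, in acceptance order
    curve: pd.DataFrame             # columns n, rmse, nrmse, r2 (per acceptance)
    rejected_indices: list
    library: SpectralLibrary        # accepted samples, all original bands
    converged_early: bool = False


def ebd_distance(x_u, X_train):
    """Squared Euclidean distances from a candidate to every training sample,
    and the diversity score (distance to the nearest one)."""
    x_u = np.asarray(x_u, float).ravel()
    X_train = np.atleast_2d(np.asarray(X_train, float))
    if X_train.shape[0] == 0:
        raise ValidationError("training set is empty")
    if X_train.shape[1] != x_u.size:
        raise ValidationError("candidate/training feature mismatch")
    d = ((X_train - x_u) ** 2).sum(axis=1)
    return d, float(d.min())


def _diversity_scores(X_pool, X_train):
    """Vectorized min squared distance from each pool row to the training set."""
    pp = (X_pool * X_pool).sum(1)[:, None]
    tt = (X_train * X_train).sum(1)[None, :]
    d = np.clip(pp + tt - 2.0 * X_pool @ X_train.T, 0.0, None)
    return d.min(axis=1)


def ebd_select(X_pool, X_train, pool_indices=None) -> int:
    """Index (into the pool) of the most remote candidate; ties broken by
    lowest index for determinism."""
    X_pool = np.atleast_2d(np.asarray(X_pool, float))
    if X_pool.shape[0] == 0:
        raise ValidationError("pool is empty")
    scores = _diversity_scores(X_pool, np.atleast_2d(np.asarray(X_train, float)))
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return best if pool_indices is None else int(np.asarray(pool_indices)[best])


def al_run(pool: SpectralLibrary, reference: SpectralLibrary, variable: str,
           config: ALConfig | None = None) -> ALResult:
    """Run EBD active learning for one trait against a reference set.

    The accept rule is strict: a proposed sample joins the training set only
    if the reference-set RMSE of the retrained model decreases; otherwise it
    is discarded from the pool for good.  The learning-curve RMSE is
    therefore non-increasing by construction.
    """
    config = config or ALConfig()
    config.validate(pool.n_samples)
    y_pool = pool.targets(variable)
    y_ref = reference.targets(variable)
    if pool.n_bands != reference.n_bands or not np.allclose(
        pool.wavelengths, reference.wavelengths
    ):
        raise ValidationError("pool and reference must share one band grid")

    # In-loop compression: PCA fitted on the pool, reference projected with
    # the same transform.  Only for loop efficiency — the returned library
    # preserves all bands.
    n_comp = min(config.n_components, pool.n_bands, pool.n_samples - 1)
    pca = pca_fit(pool.reflectance, n_components=n_comp)
    Z_pool = pca_transform(pca, pool.reflectance)
    Z_ref = pca_transform(pca, reference.reflectance)

    rng = np.random.default_rng(config.seed)
    all_idx = np.arange(pool.n_samples)
    train_idx = list(rng.choice(all_idx, size=config.initial_size, replace=False))
    candidate_mask = np.ones(pool.n_samples, dtype=bool)
    candidate_mask[train_idx] = False

    def full_fit(idx):
        return gpr.fit(Z_pool[idx], y_pool[idx], restarts=config.gpr_restarts,
                       seed=config.seed, maxiter=config.gpr_maxiter)

    model = full_fit(train_idx)
    stats = goodness_of_fit(y_ref, gpr.predict(model, Z_ref).mean)
    best_rmse = stats.rmse
    curve_rows = [{"n": len(train_idx), "rmse": stats.rmse,
                   "nrmse": stats.nrmse, "r2": stats.r2}]
    rejected: list[int] = []
    accept_since_refit = 0
    consecutive_rejections = 0
    converged_early = False

    while len(train_idx) < config.stop_size:
        cand_pool = np.flatnonzero(candidate_mask)
        if cand_pool.size == 0:
            converged_early = True
            log.info("pool exhausted at %d accepted samples", len(train_idx))
            break
        cand = ebd_select(Z_pool[cand_pool], Z_pool[train_idx], cand_pool)
        trial_idx = train_idx + [cand]
        trial_model = gpr.refit_weights(model, Z_pool[trial_idx], y_pool[trial_idx])
        trial_stats = goodness_of_fit(y_ref, gpr.predict(trial_model, Z_ref).mean)
        candidate_mask[cand] = False
        if trial_stats.rmse < best_rmse:
            train_idx = trial_idx
            best_rmse = trial_stats.rmse
            model = trial_model
            accept_since_refit += 1
            consecutive_rejections = 0
            if accept_since_refit >= config.refit_every:
                model = full_fit(train_idx)
                accept_since_refit = 0
                refreshed = goodness_of_fit(y_ref, gpr.predict(model, Z_ref).mean)
                # Keep only a refit that also helps on the reference metric,
                # preserving the monotone learning curve.
                if refreshed.rmse <= best_rmse:
                    best_rmse = refreshed.rmse
                    trial_stats = refreshed
                else:
                    model = gpr.refit_weights(model, Z_pool[train_idx], y_pool[train_idx])
            curve_rows.append({"n": len(train_idx), "rmse": best_rmse,
                               "nrmse": trial_stats.nrmse, "r2": trial_stats.r2})
        else:
            rejected.append(int(cand))
            consecutive_rejections += 1
            if (config.max_rejections_per_step is not None
                    and consecutive_rejections >= config.max_rejections_per_step):
                converged_early = True
                log.info("stopping after %d consecutive rejections at n=%d",
                         consecutive_rejections, len(train_idx))
                break

    return ALResult(
        accepted_indices=[int(i) for i in train_idx],
        curve=pd.DataFrame(curve_rows),
        rejected_indices=rejected,
        library=pool.subset(train_idx),
        converged_early=converged_early,
    )


def random_bypass(pool: SpectralLibrary, n: int = 1000, seed: int = 0) -> SpectralLibrary:
    """Random-subset fallback for traits without reference data (FAPAR, FVC):
    draw n pool samples uniformly instead of running the AL loop."""
    if n > pool.n_samples:
        raise ValidationError(f"cannot draw {n} samples from a pool of {pool.n_samples}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.n_samples, size=n, replace=False)
    return pool.subset(np.sort(idx))


def augment_zero_spectra(library: SpectralLibrary,
                         nonveg: SpectralLibrary | None) -> SpectralLibrary:
    """Append zero-labeled non-vegetated spectra to a training library.

    Row concatenation with provenance labels retained; band grids must match.
    """
    if nonveg is None or nonveg.n_samples == 0:
        return library
    return library.concat(nonveg)
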