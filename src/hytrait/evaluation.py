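"""Goodness-of-fit statistics, map consistency, and relevance exports."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FitStats", "goodness_of_fit", "model_consistency",
           "relevance_export", "report_table"]


@dataclass
class FitStats:
    """Standard retrieval validation statistics.

    NRMSE = 100 RMSE / range(obs); RRMSE = 100 RMSE / mean(obs); R^2 is the
    squared Pearson correlation by default (``r2_definition="pearson"``) —
    the coefficient of determination on the 1:1 line is available as
    ``r2_definition="deviation"``.
    """

    n: int
    rmse: float
    rrmse: float
    nrmse: float
    r2: float


def goodness_of_fit(observed, predicted, r2_definition: str = "pearson") -> FitStats:
    obs = np.asarray(observed, float).ravel()
    pred = np.asarray(predicted, float).ravel()
    if obs.size != pred.size:
        raise ValidationError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValidationError("need at least 2 observation pairs")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    rng = obs.max() - obs.min()
    if rng <= 0:
        warnings.warn("constant observations: NRMSE undefined (NaN)", stacklevel=2)
        nrmse = np.nan
    else:
        nrmse = 100.0 * rmse / rng
    mean_obs = obs.mean()
    rrmse = 100.0 * rmse / mean_obs if mean_obs != 0 else np.nan
    if rng <= 0:
        r2 = np.nan
    elif r2_definition == "pearson":
        sd_p = pred.std()
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2) if sd_p > 0 else 0.0
    elif r2_definition == "deviation":
        ss_res = np.sum((obs - pred) ** 2)
        ss_tot = np.sum((obs - mean_obs) ** 2)
        r2 = float(1.0 - ss_res / ss_tot)
    else:
        raise ValidationError(f"unknown r2_definition {r2_definition!r}")
    return FitStats(n=obs.size, rmse=rmse, rrmse=float(rrmse),
                    nrmse=float(nrmse), r2=r2)


def model_consistency(map_a, map_b, mask=None, r2_definition: str = "pearson"):
    """Pairwise comparison of two co-registered trait maps.

    Returns ``(r2, bias, scatter)`` where bias = mean(b - a) over unmasked
    pixels and scatter is a DataFrame of the paired values (the scatter-plot
    table export).
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    if a.shape != b.shape:
        raise ValidationError("maps are not co-registered (shape mismatch)")
    valid = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        valid &= np.asarray(mask, bool)
    if not np.any(valid):
        raise ValidationError("no overlapping valid pixels")
    av, bv = a[valid].ravel(), b[valid].ravel()
    bias = float(np.mean(bv - av))
    if av.size < 2 or av.std() == 0 or bv.std() == 0:
        r2 = 1.0 if np.allclose(av + bias, bv) else np.nan
    elif r2_definition == "pearson":
        r2 = float(np.corrcoef(av, bv)[0, 1] ** 2)
    else:
        ss_res = np.sum((av - bv) ** 2)
        ss_tot = np.sum((av - av.mean()) ** 2)
        r2 = float(1.0 - ss_res / ss_tot)
    scatter = pd.DataFrame({"model_a": av, "model_b": bv})
    return r2, bias, scatter


def report_table(entries) -> pd.DataFrame:
    """Validation report: one row per (variable, strategy) pair.

    ``entries`` is an iterable of ``(label, FitStats, train_time_s,
    test_time_s)``; runtimes are informational only and may be NaN.
    """
    rows = []
    for label, stats, t_train, t_test in entries:
        rows.append({
            "Variable": label, "N": stats.n, "RMSE": stats.rmse,
            "RRMSE": stats.rrmse, "NRMSE": stats.nrmse, "R2": stats.r2,
            "train_time_s": t_train, "test_time_s": t_test,
        })
    return pd.DataFrame(rows)


def relevance_export(relevance, labels) -> pd.DataFrame:
    """Polar-plot table for per-feature relevance.

    Features are laid out at angles 2 pi k / n with radius r_m in [0, 100];
    the further out, the more relevant.  Labels are wavelengths in nm for
    band-ranking models and component indices for PCA models.
    """
    r = np.asarray(relevance, float).ravel()
    labels = list(labels)
    if len(labels) != r.size:
        raise ValidationError("labels and relevance disagree on length")
    if np.any((r < 0) | (r > 100)):
        raise ValidationError("relevance values must lie in [0, 100]")
    angles = 2.0 * np.pi * np.arange(r.size) / r.size
    return pd.DataFrame({"feature": labels, "angle_rad": angles, "radius": r})
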