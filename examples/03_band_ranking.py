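"""Rank spectral bands for one trait with sequential backward band removal.

An ARD Gaussian process assigns each band a lengthscale; large lengthscales
mean the trait barely varies along that band.  SBBR repeatedly removes the
least relevant band (by 3-fold cross-validated consensus) and retrains,
producing a full ranking and a survival table of cross-validated R^2.
"""

from hytrait import build_band_grid, gpr
from hytrait.dimred import sbbr_run, select_best_bands, select_best_band_indices
from hytrait.evaluation import relevance_export
from hytrait.workflow import build_pool
from hytrait.active_learning import random_bypass

grid = build_band_grid(400, 2500, 80, 80, "coarse80")
pool = build_pool(n=400, grid=grid, seed=3, fine_step=10, windows=None)
lib = random_bypass(pool, 150, seed=0)

result = sbbr_run(lib, "CCC", folds=3, seed=0)
print("survival table (every 5th iteration):")
print(result.table.iloc[::5][["n_bands", "r2", "sd", "min", "max"]].to_string(index=False))

k = 10
best = select_best_bands(result, k)
print(f"\ntop-{k} bands for CCC (nm):", " ".join(f"{w:g}" for w in best))

# relevance polar table from a model on the selected bands
idx = select_best_band_indices(result, k)
model = gpr.fit(lib.reflectance[:, idx], lib.targets("CCC"), restarts=2, seed=0)
rel = gpr.band_relevance(model)
table = relevance_export(rel, lib.wavelengths[idx].tolist())
print("\nrelevance polar table (radius = relevance, 0-100):")
print(table.round(2).to_string(index=False))
print("-> bands near the chlorophyll absorption and red edge should rank "
      "high for a chlorophyll-driven trait; cross-validated R^2 stays flat "
      "until informative bands start being removed.")
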