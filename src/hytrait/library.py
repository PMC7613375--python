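"""Spectral library container: the currency passed between pipeline stages.

A :class:`SpectralLibrary` couples a reflectance matrix (samples x bands) with
the band-center wavelengths and a row-aligned trait table.  Every stage of the
retrieval workflow (simulation, resampling, active learning, dimensionality
reduction, model training) consumes and produces this object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical retrievable trait columns, in reporting order.
TRAIT_NAMES = ("SLA", "LAI", "CCC", "CWC", "FAPAR", "FVC")


@dataclass
class SpectralLibrary:
    """Trait-labeled collection of reflectance spectra on a common band grid.

    Parameters
    ----------
    wavelengths
        Band centers in nm, strictly increasing, shape ``(n_bands,)``.
    reflectance
        Reflectance factors in [0, 1], shape ``(n_samples, n_bands)``.
    traits
        Row-aligned table of trait values (and optionally the raw model
        inputs that generated each spectrum).
    metadata
        Free-form provenance: generator seed, band-grid id, kept-band index
        after exclusion masking, etc.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    traits: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValidationError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValidationError(
                f"reflectance has {self.reflectance.shape[1]} bands but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if len(self.traits) != self.reflectance.shape[0]:
            raise ValidationError(
                f"trait table has {len(self.traits)} rows but reflectance has "
                f"{self.reflectance.shape[0]}"
            )
        self.traits = self.traits.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def targets(self, variable: str) -> np.ndarray:
        """Return the target vector for one trait, raising if absent."""
        if variable not in self.traits.columns:
            raise ValidationError(
                f"trait column {variable!r} not present in library "
                f"(have: {list(self.traits.columns)})"
            )
        return self.traits[variable].to_numpy(dtype=float)

    def subset(self, rows) -> "SpectralLibrary":
        """Row subset (copy); preserves wavelengths and metadata."""
        rows = np.asarray(rows)
        return SpectralLibrary(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[rows].copy(),
            traits=self.traits.iloc[rows].reset_index(drop=True),
            metadata=dict(self.metadata),
        )

    def select_bands(self, band_idx) -> "SpectralLibrary":
        """Column subset by band index (copy); records kept indices."""
        band_idx = np.asarray(band_idx, dtype=int)
        meta = dict(self.metadata)
        prev = np.asarray(meta.get("kept_band_index", np.arange(self.n_bands)))
        meta["kept_band_index"] = prev[band_idx].tolist()
        return SpectralLibrary(
            wavelengths=self.wavelengths[band_idx].copy(),
            reflectance=self.reflectance[:, band_idx].copy(),
            traits=self.traits.copy(),
            metadata=meta,
        )

    def concat(self, other: "SpectralLibrary") -> "SpectralLibrary":
        """Row-wise concatenation; band grids must match exactly."""
        if other.n_bands != self.n_bands or not np.allclose(
            other.wavelengths, self.wavelengths
        ):
            raise ValidationError("cannot concatenate libraries on different band grids")
        traits = pd.concat([self.traits, other.traits], ignore_index=True)
        return SpectralLibrary(
            wavelengths=self.wavelengths.copy(),
            reflectance=np.vstack([self.reflectance, other.reflectance]),
            traits=traits,
            metadata=dict(self.metadata),
        )


def write_spectral_library(lib: SpectralLibrary, path) -> None:
    """Write a library to CSV (full float precision) plus a sidecar JSON.

    Layout: one row per sample; columns ``sample_id``, trait columns by name,
    then one reflectance column per band named by its center wavelength in nm.
    """
    path = Path(path)
    band_cols = [f"{w:.6g}" for w in lib.wavelengths]
    df = lib.traits.copy()
    df.insert(0, "sample_id", np.arange(lib.n_samples))
    spec_df = pd.DataFrame(lib.reflectance, columns=band_cols)
    pd.concat([df, spec_df], axis=1).to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "wavelengths_nm": lib.wavelengths.tolist(),
        "trait_columns": list(lib.traits.columns),
        "metadata": _jsonable(lib.metadata),
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def read_spectral_library(path, required_traits=()) -> SpectralLibrary:
    """Read a library written by :func:`write_spectral_library`.

    ``required_traits`` columns missing from the CSV raise a
    :class:`ValidationError` naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
        trait_cols = [c for c in meta["trait_columns"] if c in df.columns]
        missing_meta = [c for c in meta["trait_columns"] if c not in df.columns]
        if missing_meta:
            raise ValidationError(f"library {path} lacks declared trait column(s) {missing_meta}")
        metadata = meta.get("metadata", {})
    else:
        # Fall back to parsing: numeric column names are bands.
        trait_cols, wl = [], []
        for c in df.columns:
            if c == "sample_id":
                continue
            try:
                wl.append(float(c))
            except ValueError:
                trait_cols.append(c)
        wavelengths = np.asarray(wl, dtype=float)
        metadata = {}
    for col in required_traits:
        if col not in df.columns:
            raise ValidationError(f"library {path} is missing required trait column {col!r}")
    band_cols = [f"{w:.6g}" for w in wavelengths]
    missing_bands = [c for c in band_cols if c not in df.columns]
    if missing_bands:
        raise ValidationError(
            f"library {path} band columns do not match the declared grid "
            f"(missing {missing_bands[:5]}...)"
        )
    return SpectralLibrary(
        wavelengths=wavelengths,
        reflectance=df[band_cols].to_numpy(dtype=float),
        traits=df[trait_cols].reset_index(drop=True),
        metadata=metadata,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
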