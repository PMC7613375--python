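"""Band grids, Gaussian spectral-response resampling, exclusion windows, cube I/O.

Imaging spectrometers such as PRISMA and the upcoming CHIME sample the
400-2500 nm range with ~10 nm bands whose per-band sensitivity is well
approximated by a Gaussian spectral response function (SRF).  This module
builds band grids, convolves fine-grid spectra with Gaussian SRFs, removes
bands inside atmospheric absorption windows, and reads/writes hyperspectral
cubes (ENVI BSQ/BIL/BIP and GeoTIFF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .library import SpectralLibrary

__all__ = [
    "BandGrid",
    "ExclusionWindows",
    "DEFAULT_EXCLUSION_WINDOWS",
    "build_band_grid",
    "gaussian_resample",
    "apply_exclusion_windows",
    "read_cube",
    "write_cube",
]


@dataclass(frozen=True)
class BandGrid:
    """Instrument band definition: centers and full-width-half-maximum, nm."""

    centers: np.ndarray
    fwhm: np.ndarray
    grid_id: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        fwhm = np.broadcast_to(np.asarray(self.fwhm, dtype=float), self.centers.shape).copy()
        object.__setattr__(self, "fwhm", fwhm)
        if np.any(np.diff(self.centers) <= 0):
            raise ValidationError("band centers must be strictly increasing")
        if np.any(fwhm <= 0):
            raise ValidationError("FWHM must be positive")

    @property
    def n_bands(self) -> int:
        return self.centers.size


@dataclass
class ExclusionWindows:
    """Closed wavelength intervals removed before model training/mapping.

    Overlapping intervals have union semantics: a band is removed when its
    center falls inside any interval.
    """

    windows: list = field(default_factory=list)  # (lo_nm, hi_nm, label)

    def __post_init__(self):
        cleaned = []
        for w in self.windows:
            lo, hi = float(w[0]), float(w[1])
            label = w[2] if len(w) > 2 else ""
            if lo > hi:
                raise ValidationError(f"exclusion window {lo}-{hi} has lo > hi")
            cleaned.append((lo, hi, label))
        self.windows = cleaned

    def contains(self, wavelengths) -> np.ndarray:
        """Boolean mask: True where a wavelength lies inside any window."""
        wl = np.asarray(wavelengths, dtype=float)
        mask = np.zeros(wl.shape, dtype=bool)
        for lo, hi, _ in self.windows:
            mask |= (wl >= lo) & (wl <= hi)
        return mask


#: Atmospheric absorption / detector-noise windows for spaceborne reflectance
#: (gaseous absorption regions where anomalous spikes and dips occur).
DEFAULT_EXCLUSION_WINDOWS = ExclusionWindows(
    [
        (535, 550, "O3/sensor artifact"),
        (755, 780, "O2-A"),  # union of the overlapping 755-775 / 755-780 listings
        (810, 855, "water vapour"),
        (885, 970, "water vapour"),
        (1015, 1050, "water vapour"),
        (1080, 1165, "water vapour"),
        (1225, 1285, "water vapour"),
        (1330, 1490, "strong water vapour"),
        (1685, 1700, "CH4"),
        (1725, 1750, "CH4"),
        (1780, 1960, "strong water vapour"),
        (1990, 2030, "CO2"),
    ]
)


def build_band_grid(start: float, stop: float, step: float, fwhm: float,
                    grid_id: str | None = None) -> BandGrid:
    """Uniform band grid: centers ``start, start+step, ... <= stop``."""
    if step <= 0:
        raise ValidationError("step must be positive")
    if fwhm <= 0:
        raise ValidationError("FWHM must be positive")
    if start > stop:
        raise ValidationError("start must not exceed stop")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    centers = start + step * np.arange(n)
    if grid_id is None:
        grid_id = f"uniform_{step:g}nm_{start:g}-{stop:g}"
    return BandGrid(centers=centers, fwhm=np.full(n, float(fwhm)), grid_id=grid_id)


#: Presets. The true CHIME grid is unpublished; these are declared stand-ins.
PRESET_GRIDS = {
    "chime10": lambda: build_band_grid(400, 2500, 10, 10, "chime10"),
    "chime7": lambda: build_band_grid(400, 2346, 7, 10, "chime7"),
}


def gaussian_resample(source_wavelengths, source_spectrum, grid: BandGrid):
    """Resample fine-grid spectra to instrument bands with Gaussian SRFs.

    Each output band is the SRF-weighted mean of source samples within
    +-2 FWHM of the band center:

        R_band = sum_i w_i R(lambda_i) / sum_i w_i,
        w_i = exp(-4 ln2 (lambda_i - c)^2 / FWHM^2).

    Truncation at +-2 FWHM with renormalization keeps the operator exact for
    constant spectra.  Bands with no source support are returned as NaN with
    a warning.

    ``source_spectrum`` may be 1-D (one spectrum) or 2-D (n_samples x n_src).
    """
    wl = np.asarray(source_wavelengths, dtype=float)
    spec = np.asarray(source_spectrum, dtype=float)
    squeeze = spec.ndim == 1
    spec = np.atleast_2d(spec)
    if spec.shape[1] != wl.size:
        raise ValidationError("source spectrum / wavelength length mismatch")
    out = np.full((spec.shape[0], grid.n_bands), np.nan)
    unsupported = []
    for b, (c, f) in enumerate(zip(grid.centers, grid.fwhm)):
        sel = np.abs(wl - c) <= 2.0 * f
        if not np.any(sel):
            unsupported.append(c)
            continue
        w = np.exp(-4.0 * np.log(2.0) * ((wl[sel] - c) / f) ** 2)
        out[:, b] = spec[:, sel] @ w / w.sum()
    if unsupported:
        warnings.warn(
            f"{len(unsupported)} band(s) had no source support within +-2 FWHM "
            f"(first: {unsupported[0]:.0f} nm); masked as NaN",
            stacklevel=2,
        )
    return out[0] if squeeze else out


def resample_library(lib: SpectralLibrary, grid: BandGrid) -> SpectralLibrary:
    """Resample every spectrum of a library to the given band grid."""
    refl = gaussian_resample(lib.wavelengths, lib.reflectance, grid)
    meta = dict(lib.metadata)
    meta["grid_id"] = grid.grid_id
    meta.pop("kept_band_index", None)
    return SpectralLibrary(
        wavelengths=grid.centers.copy(),
        reflectance=refl,
        traits=lib.traits.copy(),
        metadata=meta,
    )


def apply_exclusion_windows(obj, windows: ExclusionWindows):
    """Remove bands whose centers fall inside any exclusion window.

    Accepts a :class:`SpectralLibrary` (returns a reduced library whose
    metadata records the kept-band index) or a ``(cube, wavelengths)`` pair
    (returns the reduced pair plus the kept index).  Membership is decided by
    band centers, not band edges.
    """
    if isinstance(obj, SpectralLibrary):
        keep = ~windows.contains(obj.wavelengths)
        if not np.any(keep):
            raise ValidationError("exclusion windows removed every band")
        return obj.select_bands(np.flatnonzero(keep))
    cube, wavelengths = obj
    wavelengths = np.asarray(wavelengths, dtype=float)
    keep = np.flatnonzero(~windows.contains(wavelengths))
    if keep.size == 0:
        raise ValidationError("exclusion windows removed every band")
    return cube[..., keep], wavelengths[keep], keep


# ---------------------------------------------------------------------------
# Cube I/O: ENVI (text header + raw binary) and GeoTIFF (via tifffile)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 2: np.int16, 12: np.uint16, 1: np.uint8}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_cube(cube, path, wavelengths=None, interleave: str = "bsq",
               metadata: dict | None = None) -> None:
    """Write a (rows, cols, bands) cube.

    ``.tif``/``.tiff`` paths go through tifffile (bands stored as pages);
    anything else is written as ENVI raw binary with a text ``.hdr`` sidecar.
    """
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValidationError("cube must be (rows, cols, bands)")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        meta = {"wavelengths_nm": list(map(float, wavelengths))} if wavelengths is not None else {}
        if metadata:
            meta.update(metadata)
        tifffile.imwrite(
            path,
            np.moveaxis(cube.astype(np.float32), 2, 0),
            metadata=meta,
            photometric="minisblack",
        )
        return

    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValidationError(f"unknown interleave {interleave!r}")
    data = cube.astype(np.float32)
    rows, cols, bands = data.shape
    if interleave == "bsq":
        arr = np.moveaxis(data, 2, 0)  # (bands, rows, cols)
    elif interleave == "bil":
        arr = np.moveaxis(data, 2, 1)  # (rows, bands, cols)
    else:  # bip
        arr = data  # (rows, cols, bands)
    arr.tofile(path)
    hdr_lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.6g}" for w in wavelengths)
        hdr_lines.append("wavelength units = Nanometers")
        hdr_lines.append(f"wavelength = {{ {wl} }}")
    Path(str(path) + ".hdr").write_text("\n".join(hdr_lines) + "\n")


def _parse_envi_header(text: str) -> dict:
    fields = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if not in_braces and "=" in line:
            key, _, val = line.partition("=")
            key, val = key.strip().lower(), val.strip()
            if val.startswith("{") and not val.endswith("}"):
                in_braces, buf = True, [val.lstrip("{")]
            else:
                fields[key] = val.strip("{} ").strip()
        elif in_braces:
            if line.endswith("}"):
                buf.append(line.rstrip("}"))
                fields[key] = " ".join(buf).strip()
                in_braces = False
            else:
                buf.append(line)
    return fields


def read_cube(path):
    """Read a cube written by :func:`write_cube`.

    Returns ``(cube, wavelengths)`` with the cube as (rows, cols, bands)
    float64 and wavelengths in nm (or None if the file records none).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        wl = meta.get("wavelengths_nm")
        cube = np.moveaxis(arr, 0, 2).astype(float)
        return cube, (np.asarray(wl, dtype=float) if wl is not None else None)

    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise ValidationError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype = _ENVI_DTYPES[int(fields["data type"])]
        interleave = fields.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"malformed ENVI header {hdr_path}: {exc}") from exc
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValidationError(
            f"ENVI file size {raw.size} does not match header {rows}x{cols}x{bands}"
        )
    if interleave == "bsq":
        cube = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2)
    elif interleave == "bil":
        cube = np.moveaxis(raw.reshape(rows, bands, cols), 1, 2)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise ValidationError(f"unknown interleave {interleave!r}")
    wl = None
    if "wavelength" in fields:
        wl = np.asarray([float(x) for x in fields["wavelength"].split(",")])
        if wl.size != bands:
            raise ValidationError("wavelength list length does not match band count")
    return cube.astype(float), wl
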