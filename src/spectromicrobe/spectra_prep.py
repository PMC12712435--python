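"""Spectral preprocessing for plot-level canopy reflectance.

Implements the standard hyperspectral preparation chain used when relating
airborne imaging-spectrometer data (1 m pixels, ~5 nm bands, 380-2500 nm) to
field plots: resampling onto a common wavelength grid, circular-buffer
averaging of image patches, normalized-difference indices (NDVI, NDWI),
low-vegetation masking, removal of noisy/atmospheric bands, and vector
(L2) normalization of each spectrum.

Conventions
-----------
* Reflectance is unitless surface reflectance; negative ingest values are
  atmospheric-correction artifacts and are clipped to zero with a count.
* Index band lookup uses the nearest grid wavelength, erroring if the
  nearest band is more than 3 nm away (bands sit on an ~5 nm grid, so
  nominal wavelengths such as 804 nm are never exact).
* NDVI filtering uses a strict ``< threshold`` rule.
* Kept band ranges are closed intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, GridError

logger = logging.getLogger(__name__)

#: Band ranges (nm, closed intervals) retained after removing noisy and
#: atmospheric-absorption bands.
DEFAULT_KEEP_RANGES: tuple[tuple[float, float], ...] = (
    (403.0, 1334.0),
    (1450.0, 1785.0),
    (1971.0, 2396.0),
)

#: Maximum distance (nm) between a nominal index band and the nearest grid band.
BAND_LOOKUP_TOLERANCE_NM = 3.0


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing grid of band-centre wavelengths in nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise GridError("wavelength grid must be a non-empty 1-D array")
        if np.any(wl <= 0):
            raise GridError("wavelengths must be positive")
        if np.any(np.diff(wl) <= 0):
            raise GridError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def nearest(self, target_nm: float, tol: float = BAND_LOOKUP_TOLERANCE_NM) -> int:
        """Index of the grid band nearest ``target_nm`` within ``tol`` nm."""
        idx = int(np.argmin(np.abs(self.wavelengths - target_nm)))
        dist = abs(self.wavelengths[idx] - target_nm)
        if dist > tol:
            raise GridError(
                f"no band within {tol} nm of {target_nm} nm "
                f"(nearest is {self.wavelengths[idx]:.1f} nm)"
            )
        return idx


def default_aop_grid(n_bands: int = 426, lo: float = 380.0, hi: float = 2500.0) -> WavelengthGrid:
    """The nominal airborne-spectrometer grid: 426 bands spanning 380-2500 nm."""
    return WavelengthGrid(np.linspace(lo, hi, n_bands))


@dataclass(frozen=True)
class SpectralIndexSpec:
    """A two-band normalized-difference index (a - b) / (a + b)."""

    name: str
    band_a_nm: float
    band_b_nm: float

    def __post_init__(self) -> None:
        if self.band_a_nm == self.band_b_nm:
            raise GridError(f"{self.name}: band_a and band_b must differ")


NDVI = SpectralIndexSpec("NDVI", 804.0, 673.0)
NDWI = SpectralIndexSpec("NDWI", 860.0, 1240.0)


@dataclass
class SpectraMatrix:
    """Plot-level reflectance: rows are plots, columns are wavelengths."""

    plot_ids: list[str]
    grid: WavelengthGrid
    reflectance: np.ndarray
    n_negative_clipped: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise DataError("reflectance must be 2-D (plots x wavelengths)")
        if self.reflectance.shape[0] != len(self.plot_ids):
            raise DataError("row count must equal number of plot_ids")
        if self.reflectance.shape[1] != len(self.grid):
            raise DataError("column count must equal grid length")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(list(self.plot_ids), self.grid, self.reflectance.copy())

    def clip_negative(self) -> "SpectraMatrix":
        """Clip negative reflectance (ingest artifacts) to zero, logging a count."""
        n = int(np.sum(self.reflectance < 0))
        if n:
            logger.warning("clipped %d negative reflectance values to 0", n)
        out = SpectraMatrix(
            list(self.plot_ids), self.grid, np.clip(self.reflectance, 0.0, None)
        )
        out.n_negative_clipped = n
        return out

    # ---- I/O: CSV with first column plot_id, remaining columns named by nm ----

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.reflectance,
            columns=[f"{w:.6g}" for w in self.wavelengths],
        )
        df.insert(0, "plot_id", self.plot_ids)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectraMatrix":
        if "plot_id" not in df.columns:
            raise DataError("spectra table needs a plot_id column")
        wl = np.array([float(c) for c in df.columns if c != "plot_id"])
        vals = df.drop(columns="plot_id").to_numpy(dtype=float)
        return cls(df["plot_id"].astype(str).tolist(), WavelengthGrid(wl), vals)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpectraMatrix":
        return cls.from_dataframe(pd.read_csv(path))

    # ---- I/O: ENVI-like float32 binary (BSQ) + plain-text header ----

    def write_envi(self, stem: str | Path) -> tuple[Path, Path]:
        stem = Path(stem)
        bin_path = stem.with_suffix(".img")
        hdr_path = stem.with_suffix(".hdr")
        self.reflectance.astype("<f4").tofile(bin_path)
        wl_txt = ", ".join(f"{w:.6f}" for w in self.wavelengths)
        hdr = (
            "ENVI\n"
            f"samples = {len(self.grid)}\n"
            f"lines = {len(self.plot_ids)}\n"
            "bands = 1\ninterleave = bsq\ndata type = 4\nbyte order = 0\n"
            f"plot ids = {{{', '.join(self.plot_ids)}}}\n"
            f"wavelength = {{{wl_txt}}}\n"
        )
        hdr_path.write_text(hdr)
        return bin_path, hdr_path

    @classmethod
    def read_envi(cls, stem: str | Path) -> "SpectraMatrix":
        stem = Path(stem)
        hdr = stem.with_suffix(".hdr").read_text()
        fields: dict[str, str] = {}
        key = None
        for raw in hdr.splitlines():
            if "=" in raw:
                key, val = raw.split("=", 1)
                fields[key.strip()] = val.strip()
        n_cols = int(fields["samples"])
        n_rows = int(fields["lines"])
        wl = np.array([float(x) for x in fields["wavelength"].strip("{}").split(",")])
        ids = [s.strip() for s in fields["plot ids"].strip("{}").split(",")]
        vals = np.fromfile(stem.with_suffix(".img"), dtype="<f4").reshape(n_rows, n_cols)
        return cls(ids, WavelengthGrid(wl), vals.astype(float))


@dataclass
class ImagePatch:
    """A small gridded reflectance patch (rows x cols x bands) around one plot.

    Pixel (i, j) has its centre at ``((i + 0.5) * pixel_size_m,
    (j + 0.5) * pixel_size_m)`` in patch-local metres; ``centre_m`` is the
    plot centre in the same frame.
    """

    reflectance: np.ndarray
    centre_m: tuple[float, float]
    grid: WavelengthGrid
    pixel_size_m: float = 1.0

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 3:
            raise DataError("patch must be rows x cols x bands")
        if self.pixel_size_m <= 0:
            raise DataError("pixel spacing must be positive")
        nr, nc, nb = self.reflectance.shape
        if nb != len(self.grid):
            raise DataError("band count must match grid")
        cy, cx = self.centre_m
        if not (0 <= cy <= nr * self.pixel_size_m and 0 <= cx <= nc * self.pixel_size_m):
            raise DataError("plot centre must lie inside the patch")


def resample_spectra(spectra: SpectraMatrix, target: WavelengthGrid) -> SpectraMatrix:
    """Linearly interpolate each spectrum onto ``target`` (no extrapolation).

    Exact for spectra that are affine in wavelength.
    """
    src = spectra.wavelengths
    tgt = target.wavelengths
    outside = tgt[(tgt < src[0]) | (tgt > src[-1])]
    if outside.size:
        raise GridError(
            "target wavelengths outside source span: "
            + ", ".join(f"{w:.1f}" for w in outside[:10])
        )
    out = np.vstack([np.interp(tgt, src, row) for row in spectra.reflectance])
    return SpectraMatrix(list(spectra.plot_ids), target, out)


def buffer_mean(patch: ImagePatch, diameter_m: float = 20.0) -> tuple[np.ndarray, int]:
    """Mean spectrum over pixels whose centres fall strictly within the buffer.

    Returns ``(mean_spectrum, n_pixels)``. Membership is by pixel-centre
    distance strictly less than ``diameter_m / 2``; centres exactly on the
    radius are excluded.
    """
    if diameter_m <= patch.pixel_size_m:
        raise DataError("buffer diameter must exceed the pixel spacing")
    nr, nc, _ = patch.reflectance.shape
    s = patch.pixel_size_m
    yy = (np.arange(nr) + 0.5) * s
    xx = (np.arange(nc) + 0.5) * s
    cy, cx = patch.centre_m
    d2 = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2
    mask = d2 < (diameter_m / 2.0) ** 2
    n = int(mask.sum())
    if n == 0:
        raise DataError("no pixel centres inside the buffer")
    return patch.reflectance[mask].mean(axis=0), n


def compute_index(spectra: SpectraMatrix, spec: SpectralIndexSpec) -> np.ndarray:
    """Per-plot normalized-difference index; NaN where the denominator is 0.

    Scale-invariant: multiplying a spectrum by any positive scalar leaves
    the index unchanged, so it may be computed before or after vector
    normalization.
    """
    ia = spectra.grid.nearest(spec.band_a_nm)
    ib = spectra.grid.nearest(spec.band_b_nm)
    a = spectra.reflectance[:, ia]
    b = spectra.reflectance[:, ib]
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom != 0, (a - b) / denom, np.nan)
    return vals


def filter_by_ndvi(
    spectra: SpectraMatrix,
    threshold: float = 0.4,
    index_spec: SpectralIndexSpec = NDVI,
) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Drop plots whose NDVI is strictly below ``threshold`` (or undefined).

    Returns the surviving spectra (input order preserved) and an exclusion
    log with columns ``plot_id, reason, value``.
    """
    vals = compute_index(spectra, index_spec)
    drop = np.isnan(vals) | (vals < threshold)
    exclusions = pd.DataFrame(
        {
            "plot_id": [p for p, d in zip(spectra.plot_ids, drop) if d],
            "reason": [
                "undefined_index" if np.isnan(v) else f"{index_spec.name}<{threshold}"
                for v, d in zip(vals, drop)
                if d
            ],
            "value": vals[drop],
        }
    )
    keep = ~drop
    if not keep.any():
        logger.warning("NDVI filter removed every plot")
    kept = SpectraMatrix(
        [p for p, k in zip(spectra.plot_ids, keep) if k],
        spectra.grid,
        spectra.reflectance[keep],
    )
    return kept, exclusions


def trim_bands(
    spectra: SpectraMatrix,
    keep_ranges: Sequence[tuple[float, float]] = DEFAULT_KEEP_RANGES,
) -> SpectraMatrix:
    """Keep only bands whose wavelength lies inside a closed kept interval."""
    ranges = [(float(lo), float(hi)) for lo, hi in keep_ranges]
    for lo, hi in ranges:
        if hi <= lo:
            raise GridError(f"invalid kept range [{lo}, {hi}]")
    for (_, hi_prev), (lo_next, _) in zip(ranges, ranges[1:]):
        if lo_next <= hi_prev:
            raise GridError("kept ranges must be non-overlapping and increasing")
    wl = spectra.wavelengths
    mask = np.zeros(wl.size, dtype=bool)
    for lo, hi in ranges:
        mask |= (wl >= lo) & (wl <= hi)
    if not mask.any():
        raise GridError("band trimming removed every band")
    return SpectraMatrix(
        list(spectra.plot_ids), WavelengthGrid(wl[mask]), spectra.reflectance[:, mask]
    )


def vector_normalize(spectra: SpectraMatrix) -> SpectraMatrix:
    """Divide each spectrum by its full-spectrum Euclidean (L2) norm."""
    norms = np.linalg.norm(spectra.reflectance, axis=1)
    zero = norms == 0
    if zero.any():
        bad = [p for p, z in zip(spectra.plot_ids, zero) if z]
        raise DataError(f"all-zero spectra cannot be normalized: {', '.join(bad)}")
    return SpectraMatrix(
        list(spectra.plot_ids), spectra.grid, spectra.reflectance / norms[:, None]
    )


def prepare_spectra(
    spectra: SpectraMatrix,
    ndvi_threshold: float = 0.4,
    keep_ranges: Sequence[tuple[float, float]] = DEFAULT_KEEP_RANGES,
) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Full preparation chain: clip negatives, NDVI-mask, trim bands, normalize.

    NDVI is computed before trimming so the 673/804 nm bands are always
    available. Returns the prepared spectra plus the NDVI exclusion log.
    """
    cleaned = spectra.clip_negative()
    kept, exclusions = filter_by_ndvi(cleaned, threshold=ndvi_threshold)
    trimmed = trim_bands(kept, keep_ranges)
    return vector_normalize(trimmed), exclusions
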