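"""Endmember spectra and band resampling.

Field spectrometers deliver continuous reflectance spectra; the camera
sees narrow 10-nm bands. Following the band-averaging convention for
narrow-filter cameras, each continuous spectrum is reduced to the mean
reflectance over every band interval, and the resampled endmembers are
assembled into the ``N endmembers x B bands`` reference matrix used by
the unmixing stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandSet

#: Canonical endmember order: top/bottom leaf, top/bottom panicle, dry/wet soil.
DEFAULT_ENDMEMBER_ORDER = ("TL", "BL", "TP", "BP", "DS", "WS")


class CoverageError(ValueError):
    """The spectrum's wavelength grid does not cover a requested band."""


@dataclass
class ContinuousSpectrum:
    """A continuous reflectance spectrum on an increasing wavelength grid (nm)."""

    name: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must be matching 1-D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.reflectance < 0):
            raise ValueError("reflectance must be non-negative")


@dataclass
class EndmemberLibrary:
    """Reference reflectance matrix, one row per endmember, one column per band."""

    names: tuple[str, ...]
    matrix: np.ndarray
    bands: BandSet

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("library matrix must be 2-D (endmembers x bands)")
        if self.matrix.shape != (len(self.names), self.bands.n_bands):
            raise ValueError("library matrix shape does not match names/bands")
        if len(set(self.names)) != len(self.names):
            raise ValueError("endmember names must be unique")
        if np.any(self.matrix < 0):
            raise ValueError("library reflectances must be non-negative")

    @property
    def n_endmembers(self) -> int:
        return len(self.names)

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def subset_bands(self, centers: tuple[float, ...]) -> "EndmemberLibrary":
        """Restrict the library to the bands with the given centers."""
        idx = [self.bands.index_of(c) for c in centers]
        return EndmemberLibrary(
            names=self.names,
            matrix=self.matrix[:, idx],
            bands=BandSet(centers=tuple(self.bands.centers[i] for i in idx),
                          width=self.bands.width),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, index=list(self.names),
                          columns=[f"{c:g}" for c in self.bands.centers])
        df.index.name = "endmember"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, width: float = 10.0) -> "EndmemberLibrary":
        df = pd.read_csv(path, index_col=0)
        centers = tuple(float(c) for c in df.columns)
        return cls(names=tuple(df.index), matrix=df.to_numpy(float),
                   bands=BandSet(centers=centers, width=width))


def resample_to_bands(spectrum: ContinuousSpectrum, bands: BandSet) -> np.ndarray:
    """Mean reflectance of ``spectrum`` over each closed band interval.

    The spectrum is treated as piecewise linear between grid points; the
    band value is its exact trapezoid-rule average over
    ``[center - width/2, center + width/2]``, which handles non-uniform
    grids correctly and reduces to a plain mean on dense uniform grids.
    """
    w, r = spectrum.wavelengths, spectrum.reflectance
    out = np.empty(bands.n_bands)
    for i in range(bands.n_bands):
        lo, hi = bands.interval(i)
        if lo < w[0] or hi > w[-1]:
            raise CoverageError(
                f"spectrum {spectrum.name!r} ({w[0]:g}-{w[-1]:g} nm) does not "
                f"cover band {bands.centers[i]:g} nm ({lo:g}-{hi:g} nm)"
            )
        inner = w[(w > lo) & (w < hi)]
        grid = np.concatenate(([lo], inner, [hi]))
        vals = np.interp(grid, w, r)
        out[i] = np.trapezoid(vals, grid) / (hi - lo)
    return out


def build_library(spectra: list[ContinuousSpectrum], bands: BandSet) -> EndmemberLibrary:
    """Resample each spectrum to the camera bands and stack into a library."""
    names = [s.name for s in spectra]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate endmember names: {names}")
    matrix = np.vstack([resample_to_bands(s, bands) for s in spectra])
    return EndmemberLibrary(names=tuple(names), matrix=matrix, bands=bands)


def spectra_to_csv(spectra: list[ContinuousSpectrum], path: str | Path) -> None:
    """Write continuous spectra as CSV: wavelength_nm plus one column per endmember.

    All spectra must share one wavelength grid (the generator's do).
    """
    w0 = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != w0.shape or not np.allclose(s.wavelengths, w0):
            raise ValueError("spectra must share a common wavelength grid for CSV export")
    df = pd.DataFrame({"wavelength_nm": w0})
    for s in spectra:
        df[s.name] = s.reflectance
    df.to_csv(path, index=False)


def spectra_from_csv(path: str | Path) -> list[ContinuousSpectrum]:
    df = pd.read_csv(path)
    w = df["wavelength_nm"].to_numpy(float)
    return [ContinuousSpectrum(name=c, wavelengths=w, reflectance=df[c].to_numpy(float))
            for c in df.columns if c != "wavelength_nm"]
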