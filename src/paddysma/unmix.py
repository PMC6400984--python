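"""Fully constrained least-squares (FCLS) linear spectral unmixing.

Each pixel's reflectance spectrum rho is modelled as a linear mixture
of endmember reference spectra,

    rho = sum_i Abd_i * rho(i) + e,

with abundances constrained non-negative and summing to one. The
solver enforces the sum-to-one constraint through a heavily weighted
augmented row inside a non-negative least-squares active-set solve
(weight delta = 1e3 * max|library|), then renormalizes the tiny
residual slack in the sum; this is the standard FCLS construction for
small endmember sets.

Plot-level abundances are the arithmetic means of per-pixel abundances
over each plot's rectangle, with leaf and panicle abundances summed
over their top and bottom layers:

    Abd_L = mean(TL) + mean(BL),  Abd_P = mean(TP) + mean(BP),
    Abd_L-P = Abd_L - Abd_P.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .raster import KIND_REFLECTANCE, MultibandImage
from .speclib import EndmemberLibrary

LEAF_ENDMEMBERS = ("TL", "BL")
PANICLE_ENDMEMBERS = ("TP", "BP")


class UnmixingError(ValueError):
    pass


@dataclass
class PlotROI:
    plot_id: str
    nitrogen: float                     # nitrogen fertilizer level, kg/ha
    rect: tuple[int, int, int, int]     # (row0, col0, n_rows, n_cols), half-open

    @property
    def n_pixels(self) -> int:
        return self.rect[2] * self.rect[3]


@dataclass
class PlotLayout:
    """Rectangular plot regions of interest with nitrogen labels."""

    plots: list[PlotROI]

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise ValueError("plot_ids must be unique")

    def check_bounds(self, rows: int, cols: int) -> None:
        for p in self.plots:
            r0, c0, nr, nc = p.rect
            if r0 < 0 or c0 < 0 or nr <= 0 or nc <= 0 or r0 + nr > rows or c0 + nc > cols:
                raise ValueError(f"plot {p.plot_id} rect {p.rect} outside image {rows}x{cols}")

    def to_json(self, path: str | Path) -> None:
        obj = [{"plot_id": p.plot_id, "nitrogen": p.nitrogen, "rect": list(p.rect)}
               for p in self.plots]
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlotLayout":
        obj = json.loads(Path(path).read_text())
        return cls(plots=[PlotROI(p["plot_id"], p["nitrogen"], tuple(p["rect"]))
                          for p in obj])


@dataclass
class AbundanceMap:
    """Per-pixel abundance vectors plus the attained residual norm."""

    values: np.ndarray          # rows x cols x N
    residual_norm: np.ndarray   # rows x cols
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.residual_norm = np.asarray(self.residual_norm, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.names):
            raise ValueError("values must be rows x cols x n_endmembers")
        if self.residual_norm.shape != self.values.shape[:2]:
            raise ValueError("residual_norm shape mismatch")

    def plane(self, name: str) -> np.ndarray:
        return self.values[:, :, self.names.index(name)]

    def validate(self, abd_tol: float = 1e-9, sum_tol: float = 1e-6) -> None:
        v = self.values
        if v.min() < -abd_tol or v.max() > 1 + abd_tol:
            raise UnmixingError("abundances outside [0, 1]")
        s = v.sum(axis=2)
        if np.max(np.abs(s - 1.0)) > sum_tol:
            raise UnmixingError("abundance sums deviate from 1")
        if self.residual_norm.min() < 0:
            raise UnmixingError("negative residual norm")


def _augmented_system(library: EndmemberLibrary) -> tuple[np.ndarray, float]:
    E = library.matrix                     # N x B
    delta = 1e3 * np.abs(E).max()
    A = np.vstack([E.T, delta * np.ones(E.shape[0])])   # (B+1) x N
    return A, delta


def fcls_pixel(spectrum: np.ndarray, library: EndmemberLibrary) -> tuple[np.ndarray, float]:
    """FCLS abundances and residual norm for one pixel spectrum.

    Minimizes ``||rho - E^T a||_2`` subject to ``a >= 0`` and
    ``sum(a) = 1``; returns ``(a, residual_norm)``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if library.n_endmembers < 2:
        raise UnmixingError("unmixing needs at least two endmembers")
    if spectrum.shape != (library.bands.n_bands,):
        raise UnmixingError(
            f"spectrum has shape {spectrum.shape}, library expects "
            f"({library.bands.n_bands},)")
    if not np.all(np.isfinite(spectrum)):
        raise UnmixingError("non-finite spectrum")
    if library.bands.n_bands < library.n_endmembers - 1:
        warnings.warn("fewer bands than endmembers - 1; abundances may be ill-determined",
                      stacklevel=2)
    A, delta = _augmented_system(library)
    b = np.concatenate([spectrum, [delta]])
    a, _ = nnls(A, b)
    s = a.sum()
    if s <= 0:  # degenerate (e.g. all-zero library); minimum-norm feasible fallback
        a = np.full(library.n_endmembers, 1.0 / library.n_endmembers)
    else:
        a = a / s
    resid = spectrum - library.matrix.T @ a
    return a, float(np.linalg.norm(resid))


def unmix_image(image: MultibandImage, library: EndmemberLibrary) -> AbundanceMap:
    """Apply :func:`fcls_pixel` to every pixel of a reflectance image."""
    if image.kind != KIND_REFLECTANCE:
        raise UnmixingError(f"expected a reflectance image, got kind={image.kind!r}")
    if image.shape[2] != library.bands.n_bands:
        raise UnmixingError(
            f"image has {image.shape[2]} bands, library has {library.bands.n_bands}")
    rows, cols, B = image.shape
    N = library.n_endmembers
    A, delta = _augmented_system(library)
    ET = library.matrix.T
    flat = image.values.reshape(-1, B)
    out = np.empty((flat.shape[0], N))
    b = np.empty(B + 1)
    b[B] = delta
    for k in range(flat.shape[0]):
        b[:B] = flat[k]
        a, _ = nnls(A, b)
        s = a.sum()
        out[k] = a / s if s > 0 else 1.0 / N
    resid = np.linalg.norm(flat - out @ library.matrix, axis=1)
    return AbundanceMap(values=out.reshape(rows, cols, N),
                        residual_norm=resid.reshape(rows, cols),
                        names=library.names)


def aggregate_abundance(abund: AbundanceMap, layout: PlotLayout) -> pd.DataFrame:
    """Plot-level abundance table.

    One row per plot: per-endmember ROI means plus the layer sums
    ``Abd_L`` (leaf), ``Abd_P`` (panicle) and their difference
    ``Abd_L-P``.
    """
    rows, cols = abund.residual_norm.shape
    layout.check_bounds(rows, cols)
    records = []
    for p in layout.plots:
        r0, c0, nr, nc = p.rect
        if nr * nc == 0:
            raise UnmixingError(f"plot {p.plot_id} has an empty ROI")
        block = abund.values[r0:r0 + nr, c0:c0 + nc, :].reshape(-1, len(abund.names))
        means = block.mean(axis=0)
        rec = {"plot_id": p.plot_id, "nitrogen": p.nitrogen, "n_pixels": nr * nc}
        rec.update({name: m for name, m in zip(abund.names, means)})
        abd_l = sum(rec[n] for n in LEAF_ENDMEMBERS if n in rec)
        abd_p = sum(rec[n] for n in PANICLE_ENDMEMBERS if n in rec)
        rec["Abd_L"] = abd_l
        rec["Abd_P"] = abd_p
        rec["Abd_L-P"] = abd_l - abd_p
        records.append(rec)
    return pd.DataFrame.from_records(records)
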