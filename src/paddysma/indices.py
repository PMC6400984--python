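"""Vegetation indices over band reflectance.

The registry holds the ten indices evaluated in the yield analysis,
written over the band reflectances rho490, rho550, rho670, rho720 and
rho800 (the 900 nm band enters unmixing only). VARI is implemented as
the green-red normalized difference (rho550 - rho670)/(rho550 + rho670),
i.e. without the blue term of the canonical atmospherically-resistant
formulation — see the methods note.

Indices are computed per pixel first and then averaged over the plot
rectangle; pixels whose denominator magnitude falls below 1e-9 (e.g.
MTCI on soil pixels where rho720 ~ rho670) are masked invalid and
excluded from plot means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .raster import KIND_REFLECTANCE, MultibandImage
from .unmix import PlotLayout

DENOM_GUARD = 1e-9


class IndexError_(KeyError):
    """Unknown vegetation index name."""


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class VIDefinition:
    name: str
    required_bands: tuple[float, ...]
    numerator: Callable[..., np.ndarray]
    denominator: Callable[..., np.ndarray]
    long_name: str = ""


def _ratio_vi(name, bands, num, den, long_name=""):
    return VIDefinition(name=name, required_bands=bands, numerator=num,
                        denominator=den, long_name=long_name)


# Each index is expressed as numerator/denominator so the denominator
# guard applies uniformly. b is a dict: center wavelength -> plane.
VI_REGISTRY: dict[str, VIDefinition] = {v.name: v for v in [
    _ratio_vi("SR", (670.0, 800.0),
              lambda b: b[800.0],
              lambda b: b[670.0],
              "Simple Ratio"),
    _ratio_vi("CI_rededge", (720.0, 800.0),
              lambda b: b[800.0] - b[720.0],
              lambda b: b[720.0],
              "Red-edge Chlorophyll Index"),
    _ratio_vi("CI_green", (550.0, 800.0),
              lambda b: b[800.0] - b[550.0],
              lambda b: b[550.0],
              "Green-edge Chlorophyll Index"),
    _ratio_vi("NDVI", (670.0, 800.0),
              lambda b: b[800.0] - b[670.0],
              lambda b: b[800.0] + b[670.0],
              "Normalized Difference Vegetation Index"),
    _ratio_vi("GNDVI", (550.0, 800.0),
              lambda b: b[800.0] - b[550.0],
              lambda b: b[800.0] + b[550.0],
              "Green Normalized Difference Vegetation Index"),
    _ratio_vi("NDRE", (720.0, 800.0),
              lambda b: b[800.0] - b[720.0],
              lambda b: b[800.0] + b[720.0],
              "Normalized Difference Red edge"),
    _ratio_vi("VARI", (550.0, 670.0),
              lambda b: b[550.0] - b[670.0],
              lambda b: b[550.0] + b[670.0],
              "Visible Atmospherically Resistant Index (green-red form)"),
    _ratio_vi("MTCI", (670.0, 720.0, 800.0),
              lambda b: b[800.0] - b[720.0],
              lambda b: b[720.0] - b[670.0],
              "MERIS Terrestrial Chlorophyll Index"),
    _ratio_vi("EVI", (490.0, 670.0, 800.0),
              lambda b: 2.5 * (b[800.0] - b[670.0]),
              lambda b: b[800.0] + 6.0 * b[670.0] - 7.5 * b[490.0] + 1.0,
              "Enhanced Vegetation Index"),
    _ratio_vi("EVI2", (670.0, 800.0),
              lambda b: 2.5 * (b[800.0] - b[670.0]),
              lambda b: b[800.0] + 2.4 * b[670.0] + 1.0,
              "Two-band Enhanced Vegetation Index"),
]}

DEFAULT_VI_NAMES = tuple(VI_REGISTRY)


@dataclass
class VIImage:
    """A per-pixel vegetation index plane with a validity mask."""

    name: str
    values: np.ndarray   # rows x cols, NaN where invalid
    valid: np.ndarray    # rows x cols bool


def get_vi(name: str) -> VIDefinition:
    try:
        return VI_REGISTRY[name]
    except KeyError:
        raise IndexError_(f"unknown vegetation index {name!r}; "
                          f"known: {sorted(VI_REGISTRY)}") from None


def compute_vi(image: MultibandImage, vi: VIDefinition | str) -> VIImage:
    """Evaluate one index per pixel, masking near-zero denominators."""
    if isinstance(vi, str):
        vi = get_vi(vi)
    if image.kind != KIND_REFLECTANCE:
        raise ValueError(f"expected a reflectance image, got kind={image.kind!r}")
    planes = {c: image.band(c) for c in vi.required_bands}
    num = vi.numerator(planes)
    den = vi.denominator(planes)
    valid = np.abs(den) >= DENOM_GUARD
    values = np.full(num.shape, np.nan)
    np.divide(num, den, out=values, where=valid)
    return VIImage(name=vi.name, values=values, valid=valid)


def aggregate_vi(vi_image: VIImage, layout: PlotLayout) -> pd.DataFrame:
    """Plot means of a VI plane over valid pixels, with invalid fractions."""
    rows, cols = vi_image.values.shape
    layout.check_bounds(rows, cols)
    records = []
    for p in layout.plots:
        r0, c0, nr, nc = p.rect
        vals = vi_image.values[r0:r0 + nr, c0:c0 + nc]
        ok = vi_image.valid[r0:r0 + nr, c0:c0 + nc]
        n_valid = int(ok.sum())
        if n_valid == 0:
            raise AggregationError(
                f"plot {p.plot_id}: all pixels masked for {vi_image.name}")
        records.append({
            "plot_id": p.plot_id,
            vi_image.name: float(vals[ok].mean()),
            f"{vi_image.name}_invalid_fraction": 1.0 - n_valid / ok.size,
        })
    return pd.DataFrame.from_records(records)


def compute_plot_vi_table(image: MultibandImage, layout: PlotLayout,
                          vi_names: tuple[str, ...] = DEFAULT_VI_NAMES,
                          of_mean_reflectance: bool = False) -> pd.DataFrame:
    """Plot-level values for several indices, merged into one table.

    By default each index is computed per pixel and then averaged over
    the plot rectangle. ``of_mean_reflectance=True`` switches to the
    alternative convention — the index of the plot-mean reflectance —
    for sensitivity analysis only.
    """
    if of_mean_reflectance:
        return _vi_of_mean_reflectance(image, layout, vi_names)
    table: pd.DataFrame | None = None
    for name in vi_names:
        part = aggregate_vi(compute_vi(image, name), layout)
        table = part if table is None else table.merge(part, on="plot_id")
    return table


def _vi_of_mean_reflectance(image: MultibandImage, layout: PlotLayout,
                            vi_names: tuple[str, ...]) -> pd.DataFrame:
    rows, cols, _ = image.shape
    layout.check_bounds(rows, cols)
    records = []
    for p in layout.plots:
        r0, c0, nr, nc = p.rect
        mean_spec = image.values[r0:r0 + nr, c0:c0 + nc, :].mean(axis=(0, 1))
        pixel = MultibandImage(values=mean_spec[None, None, :],
                               bands=image.bands, kind=image.kind)
        rec = {"plot_id": p.plot_id}
        for name in vi_names:
            out = compute_vi(pixel, name)
            if not out.valid[0, 0]:
                raise AggregationError(
                    f"plot {p.plot_id}: mean-reflectance denominator vanishes "
                    f"for {name}")
            rec[name] = float(out.values[0, 0])
        records.append(rec)
    return pd.DataFrame.from_records(records)
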