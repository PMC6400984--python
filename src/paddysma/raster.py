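"""Multi-band raster container and TIFF I/O.

Images are held as float64 ``rows x cols x bands`` arrays tagged with
their :class:`~paddysma.bands.BandSet` and a ``kind`` that records
whether values are raw digital numbers (DN) or surface reflectance.
On disk they are plain multi-band float32 TIFFs (band-interleaved,
``bands x rows x cols``) carrying band metadata in the description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .bands import BandSet

KIND_DN = "dn"
KIND_REFLECTANCE = "reflectance"


@dataclass
class MultibandImage:
    """A ``rows x cols x bands`` raster with band metadata.

    ``kind`` is ``"dn"`` for raw digital numbers or ``"reflectance"``
    for calibrated surface reflectance fractions.
    """

    values: np.ndarray
    bands: BandSet
    kind: str = KIND_DN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be rows x cols x bands")
        if self.values.shape[2] != self.bands.n_bands:
            raise ValueError(
                f"band axis ({self.values.shape[2]}) does not match "
                f"BandSet ({self.bands.n_bands})"
            )
        if self.kind not in (KIND_DN, KIND_REFLECTANCE):
            raise ValueError(f"unknown image kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def band(self, center: float) -> np.ndarray:
        """The 2-D plane for the band centered at ``center`` nm."""
        return self.values[:, :, self.bands.index_of(center)]

    def write(self, path: str | Path) -> None:
        """Write as multi-band float32 TIFF with band metadata."""
        meta = {
            "kind": self.kind,
            "band_centers_nm": list(self.bands.centers),
            "band_width_nm": self.bands.width,
        }
        planar = np.ascontiguousarray(np.moveaxis(self.values, 2, 0).astype(np.float32))
        tifffile.imwrite(str(path), planar, photometric="minisblack",
                         description=json.dumps(meta))

    @classmethod
    def read(cls, path: str | Path) -> "MultibandImage":
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc) if desc else {}
        if arr.ndim == 2:
            arr = arr[None, :, :]
        values = np.moveaxis(arr, 0, 2).astype(float)
        bands = BandSet(
            centers=tuple(meta.get("band_centers_nm", range(values.shape[2]))),
            width=float(meta.get("band_width_nm", 10.0)),
        )
        return cls(values=values, bands=bands, kind=meta.get("kind", KIND_DN))


def plane_stack(planes: dict[str, np.ndarray], path: str | Path,
                kind: str = "abundance", as_gray_uint8: bool = False) -> None:
    """Write named 2-D planes (e.g. per-endmember abundances) as one TIFF.

    Planes are float32 by default; ``as_gray_uint8`` exports a 0-255
    gray rendering (values clipped to [0, 1]) for visual inspection.
    """
    names = list(planes)
    arr = np.stack([planes[n] for n in names])
    if as_gray_uint8:
        arr = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr, photometric="minisblack",
                     description=json.dumps({"kind": kind, "planes": names}))
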