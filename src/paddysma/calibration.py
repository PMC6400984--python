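"""Empirical-line radiometric calibration.

Ground panels of known reflectance appear in the image; assuming a
linear sensor response, per-band gain/offset pairs are fitted by
ordinary least squares of panel nominal reflectance on panel-mean DN,
then applied pixel-wise:

    rho_b = DN_b * gain_b + offset_b

Reflectance is deliberately NOT clipped to [0, 1]: clipping would bias
both vegetation indices and unmixing. A QC summary reports the
out-of-range fraction instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .raster import KIND_DN, KIND_REFLECTANCE, MultibandImage

#: Nominal reflectances of the standard four-panel calibration target set.
DEFAULT_PANEL_REFLECTANCES = (0.06, 0.24, 0.48, 1.0)

Rect = tuple[int, int, int, int]  # (row0, col0, n_rows, n_cols), 0-based half-open


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationTargetSet:
    """Calibration panels: (nominal reflectance, image rectangle) pairs."""

    panels: list[tuple[float, Rect]]

    def __post_init__(self) -> None:
        if len(self.panels) < 2:
            raise CalibrationError("need at least two calibration panels")
        noms = [np.atleast_1d(np.asarray(p[0], dtype=float)) for p in self.panels]
        for a, b in ((a, b) for i, a in enumerate(noms) for b in noms[i + 1:]):
            if a.shape == b.shape and np.array_equal(a, b):
                raise CalibrationError("panel nominal reflectances must be distinct")
        for nom in noms:
            if np.any(nom <= 0) or np.any(nom > 1.2):
                raise CalibrationError(
                    f"nominal reflectance {nom} outside (0, 1.2]")

    def to_json(self, path: str | Path) -> None:
        obj = [{"reflectance": (list(np.asarray(nom, dtype=float))
                                if np.ndim(nom) else float(nom)),
                "rect": list(rect)} for nom, rect in self.panels]
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTargetSet":
        obj = json.loads(Path(path).read_text())
        return cls(panels=[(p["reflectance"], tuple(p["rect"])) for p in obj])


@dataclass
class CalibrationModel:
    """Per-band affine DN -> reflectance model with panel residuals."""

    gain: np.ndarray       # reflectance per DN, one per band
    offset: np.ndarray     # reflectance, one per band
    residuals: np.ndarray = field(default=None)  # panels x bands, nominal - fitted

    def __post_init__(self) -> None:
        self.gain = np.atleast_1d(np.asarray(self.gain, dtype=float))
        self.offset = np.atleast_1d(np.asarray(self.offset, dtype=float))
        if self.gain.shape != self.offset.shape:
            raise CalibrationError("gain and offset must have one value per band")
        if not (np.all(np.isfinite(self.gain)) and np.all(np.isfinite(self.offset))):
            raise CalibrationError("non-finite calibration coefficients")
        if np.any(self.gain == 0):
            raise CalibrationError("zero gain is not invertible")
        if self.residuals is not None:
            self.residuals = np.asarray(self.residuals, dtype=float)

    @property
    def n_bands(self) -> int:
        return self.gain.shape[0]


def panel_mean_dn(dn_image: MultibandImage, targets: CalibrationTargetSet) -> np.ndarray:
    """Arithmetic mean DN per panel per band (panels x bands)."""
    rows, cols, _ = dn_image.shape
    means = []
    for nom, (r0, c0, nr, nc) in targets.panels:
        if r0 < 0 or c0 < 0 or r0 + nr > rows or c0 + nc > cols or nr <= 0 or nc <= 0:
            raise CalibrationError(f"panel rect {(r0, c0, nr, nc)} outside image {rows}x{cols}")
        means.append(dn_image.values[r0:r0 + nr, c0:c0 + nc, :].reshape(-1, dn_image.shape[2]).mean(axis=0))
    return np.vstack(means)


def fit_empirical_line(dn_image: MultibandImage,
                       targets: CalibrationTargetSet) -> CalibrationModel:
    """Fit per-band (gain, offset) by OLS over the panel-mean DNs.

    Per band b this solves ``nominal = DN_b * gain_b + offset_b`` in the
    least-squares sense across panels — the normal-equation form of the
    empirical line method.
    """
    if dn_image.kind != KIND_DN:
        raise CalibrationError(f"expected a DN image, got kind={dn_image.kind!r}")
    dn = panel_mean_dn(dn_image, targets)                       # panels x bands
    # nominals may be scalars (wavelength-constant panels, the default)
    # or per-band vectors
    nominal = np.array([np.broadcast_to(np.asarray(p[0], dtype=float),
                                        (dn.shape[1],))
                        for p in targets.panels])               # panels x bands
    n_bands = dn.shape[1]
    gain = np.empty(n_bands)
    offset = np.empty(n_bands)
    resid = np.empty_like(dn)
    for b in range(n_bands):
        x = dn[:, b]
        if np.ptp(x) == 0:
            raise CalibrationError(
                f"identical panel-mean DNs in band {b}; design is singular")
        design = np.column_stack([np.ones_like(x), x])
        (off, g), *_ = np.linalg.lstsq(design, nominal[:, b], rcond=None)
        gain[b], offset[b] = g, off
        resid[:, b] = nominal[:, b] - (x * g + off)
    return CalibrationModel(gain=gain, offset=offset, residuals=resid)


def apply_calibration(dn_image: MultibandImage, model: CalibrationModel) -> MultibandImage:
    """Apply the per-band affine transform; output kind is reflectance (unclipped)."""
    if dn_image.shape[2] != model.n_bands:
        raise CalibrationError(
            f"image has {dn_image.shape[2]} bands, model has {model.n_bands}")
    refl = dn_image.values * model.gain + model.offset
    return MultibandImage(values=refl, bands=dn_image.bands, kind=KIND_REFLECTANCE)


def calibration_qc(refl_image: MultibandImage) -> dict:
    """Fraction of out-of-range reflectance values (<0 or >1), per band and overall."""
    v = refl_image.values
    per_band = ((v < 0) | (v > 1)).mean(axis=(0, 1))
    return {
        "out_of_range_fraction": float(per_band.mean()),
        "out_of_range_fraction_per_band": [float(f) for f in per_band],
    }
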