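"""Camera band definitions.

The six-camera array carries narrow band-pass filters; each band is
described by its center wavelength and a common full width. The default
set is the 490/550/670/720/800/900 nm, 10 nm configuration used for
paddy-field canopy imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandSet:
    """An ordered set of narrow spectral bands.

    Parameters
    ----------
    centers : tuple of float
        Band center wavelengths in nm, strictly increasing.
    width : float
        Full band width in nm (common to all bands).
    """

    centers: tuple[float, ...] = (490.0, 550.0, 670.0, 720.0, 800.0, 900.0)
    width: float = 10.0

    def __post_init__(self) -> None:
        centers = tuple(float(c) for c in self.centers)
        object.__setattr__(self, "centers", centers)
        if len(centers) == 0:
            raise ValueError("BandSet needs at least one band")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")
        if not self.width > 0:
            raise ValueError("band width must be positive")

    @property
    def n_bands(self) -> int:
        return len(self.centers)

    def interval(self, i: int) -> tuple[float, float]:
        """Closed wavelength interval [center - width/2, center + width/2] of band i."""
        c = self.centers[i]
        return (c - self.width / 2.0, c + self.width / 2.0)

    def index_of(self, center: float, tol: float = 0.5) -> int:
        """Index of the band whose center is within ``tol`` nm of ``center``."""
        for i, c in enumerate(self.centers):
            if abs(c - center) <= tol:
                return i
        raise KeyError(f"no band centered near {center} nm in {self.centers}")


DEFAULT_BANDS = BandSet()
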