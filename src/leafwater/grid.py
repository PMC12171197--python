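"""Wavelength grids: the coordinate system every spectral quantity lives on.

A grid is an ordered list of band centers in nanometres.  Downstream code
takes the grid as data and never assumes uniform spacing — push-broom NIR
imagers typically have slightly non-uniform band centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centers in nm; strictly increasing, length >= 2."""

    centers_nm: np.ndarray = field()

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers_nm, dtype=float)
        object.__setattr__(self, "centers_nm", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("grid needs at least 2 band centers")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.centers_nm.size)

    def nearest(self, nm: float) -> int:
        """Index of the band center closest to ``nm`` (lowest index on ties)."""
        return int(np.argmin(np.abs(self.centers_nm - nm)))

    def require_cover(self, nm: float, what: str = "anchor") -> int:
        """Nearest band index, erroring if ``nm`` lies outside the grid span."""
        lo, hi = self.centers_nm[0], self.centers_nm[-1]
        if not (lo <= nm <= hi):
            raise ValueError(
                f"grid [{lo:.2f}, {hi:.2f}] nm does not cover {what} at {nm:g} nm"
            )
        return self.nearest(nm)

    @property
    def mean_spacing_nm(self) -> float:
        return float(np.mean(np.diff(self.centers_nm)))


def default_grid(n_bands: int = 224, start_nm: float = 900.0, end_nm: float = 1700.0) -> WavelengthGrid:
    """Uniform NIR grid emulating a 224-band 900-1700 nm line-scan imager."""
    if n_bands < 4:
        raise ValueError("n_bands must be >= 4")
    if not start_nm < end_nm:
        raise ValueError("start_nm must be < end_nm")
    return WavelengthGrid(np.linspace(start_nm, end_nm, n_bands))
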