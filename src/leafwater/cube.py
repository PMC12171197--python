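"""Hyperspectral cube I/O, reflectance calibration and leaf extraction.

Cubes travel in the ENVI interchange format: an ASCII header file
describing shape, interleave (BIL/BIP/BSQ), data type and the wavelength
list, next to a raw binary array.  Raw intensity is converted to
reflectance with a white reference panel and a dark-current frame:

    R = (I - B) / (W - B)

Leaf/background segmentation is a transparent linear pixel classifier (or,
unsupervised, an Otsu threshold on a two-band contrast ratio); the mean
spectrum over the leaf mask is the per-sample reflectance used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .grid import WavelengthGrid

__all__ = [
    "HyperCube",
    "CalibrationFrames",
    "read_envi",
    "write_envi",
    "calibrate",
    "segment_leaf",
    "mean_spectrum",
    "write_mask_png",
    "read_mask_png",
]

# ENVI numeric codes for the dtypes we support losslessly
_ENVI_DTYPES = {2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """Calibrated reflectance image: rows x cols x bands plus a leaf mask."""

    data: np.ndarray
    grid: WavelengthGrid
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != len(self.grid):
            raise ValueError("band dimension must equal grid length")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite reflectance")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask must match the cube's spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def leaf_pixels(self) -> np.ndarray:
        """(n_leaf_pixels, bands) matrix of masked spectra."""
        return self.data[self.mask]


@dataclass
class CalibrationFrames:
    """Raw intensity cube plus white-reference and dark-current frames.

    White/dark frames may be single scan lines (shape (1, cols, bands)),
    the push-broom convention; they broadcast along the scan axis.
    """

    raw: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.raw.ndim != 3:
            raise ValueError("raw cube must be rows x cols x bands")
        for name, frame in (("white", self.white), ("dark", self.dark)):
            if frame.ndim != 3 or frame.shape[1:] != self.raw.shape[1:]:
                raise ValueError(f"{name} frame not conformable with raw cube")
            if frame.shape[0] not in (1, self.raw.shape[0]):
                raise ValueError(f"{name} frame must have 1 or {self.raw.shape[0]} lines")
        if self.raw.shape[2] != len(self.grid):
            raise ValueError("band count must equal grid length")


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI ``key = value`` pairs; brace-delimited values may span lines."""
    header: dict = {}
    lines = iter(text.splitlines())
    for line in lines:
        line = line.strip()
        if not line or line.upper() == "ENVI" or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value:
                value += " " + next(lines).strip()
            value = value.strip("{} ").strip()
        header[key] = value
    return header


def read_envi(header_path, data_path=None) -> HyperCube:
    """Read an ENVI cube (header + raw binary); mask is all-true."""
    header_path = Path(header_path)
    text = header_path.read_text()
    hdr = _parse_envi_header(text)
    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in hdr:
            raise ValueError(f"ENVI header missing required field '{key}'")
    if "wavelength" not in hdr:
        raise ValueError("ENVI header missing required field 'wavelength'")
    samples, lines, bands = (int(hdr[k]) for k in ("samples", "lines", "bands"))
    interleave = hdr["interleave"].lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    code = int(hdr["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    wavelengths = np.array([float(w) for w in hdr["wavelength"].split(",") if w.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but wavelength list has {wavelengths.size} entries"
        )
    if data_path is None:
        data_path = header_path.with_suffix("." + interleave)
    flat = np.fromfile(data_path, dtype=_ENVI_DTYPES[code])
    if flat.size != samples * lines * bands:
        raise ValueError("binary size does not match header-declared shape")
    if interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    return HyperCube(data=np.ascontiguousarray(data), grid=WavelengthGrid(wavelengths))


def write_envi(cube: HyperCube, header_path, data_path=None, interleave: str = "bil") -> None:
    """Write an ENVI header + raw binary pair; round trips losslessly."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype} for ENVI export")
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix("." + interleave)
    lines, samples, bands = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.centers_nm)
    header_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    if interleave == "bip":
        out = cube.data
    elif interleave == "bil":
        out = cube.data.transpose(0, 2, 1)
    else:
        out = cube.data.transpose(2, 0, 1)
    np.ascontiguousarray(out).tofile(data_path)


def calibrate(frames: CalibrationFrames) -> HyperCube:
    """Black/white calibration: ``R = (I - B) / (W - B)`` elementwise."""
    denom = frames.white - frames.dark
    bad = denom <= 0
    if bad.any():
        idx = np.argwhere(bad)[:10]
        raise ValueError(
            f"white - dark is non-positive at {int(bad.sum())} entries, "
            f"e.g. (line, col, band) {[tuple(i) for i in idx]}"
        )
    refl = (frames.raw - frames.dark) / denom  # frames broadcast along scan axis
    return HyperCube(data=refl, grid=frames.grid)


def segment_leaf(
    cube: HyperCube,
    labeled_pixels: tuple[np.ndarray, np.ndarray] | None = None,
    bright_nm: float = 1070.0,
    absorb_nm: float = 1440.0,
) -> np.ndarray:
    """Leaf/background mask for a calibrated cube.

    With ``labeled_pixels`` (``(coords, labels)``: (k,2) row/col array and a
    boolean label vector, True = leaf) a linear two-class classifier is
    trained on the labelled spectra.  Without labels, an Otsu threshold is
    applied to the per-pixel ratio of a high-reflectance band to the 1440 nm
    water-absorption band — large for leaf tissue, near 1 for flat
    background — which is invariant to band-wise constant rescaling.
    """
    h, w, _ = cube.shape
    if labeled_pixels is not None:
        from sklearn.linear_model import LogisticRegression

        coords, labels = labeled_pixels
        coords = np.asarray(coords, dtype=int)
        labels = np.asarray(labels, dtype=bool)
        if labels.all() or not labels.any():
            raise ValueError("training set must contain both leaf and background pixels")
        spectra = cube.data[coords[:, 0], coords[:, 1]]
        clf = LogisticRegression(max_iter=1000).fit(spectra, labels)
        mask = clf.predict(cube.data.reshape(-1, cube.shape[2])).reshape(h, w)
        return mask.astype(bool)

    from skimage.filters import threshold_otsu

    def window_mean(nm: float, what: str, half_width_nm: float = 50.0) -> np.ndarray:
        cube.grid.require_cover(nm, what)
        sel = np.abs(cube.grid.centers_nm - nm) <= half_width_nm
        return cube.data[:, :, sel].mean(axis=2)

    # averaging a +-50 nm window suppresses single-band noise on dark pixels
    eps = 1e-12
    ratio = window_mean(bright_nm, "contrast band") / np.maximum(
        window_mean(absorb_nm, "water-absorption band"), eps
    )
    thr = threshold_otsu(ratio)
    mask = ratio > thr
    # Otsu always splits; accept only if leaf tissue shows real water
    # contrast (>15% bright/absorbing ratio excess, scale-invariant)
    lo, hi = ratio[~mask], ratio[mask]
    if mask.all() or not mask.any() or hi.mean() < 1.15 * lo.mean():
        warnings.warn("no leaf-like pixels found; returning an empty mask")
        return np.zeros((h, w), dtype=bool)
    return mask


def mean_spectrum(cube: HyperCube) -> np.ndarray:
    """Per-band arithmetic mean reflectance over the leaf mask."""
    if not cube.mask.any():
        raise ValueError("mask is empty: no leaf pixels to average")
    return cube.leaf_pixels().mean(axis=0)


def write_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8), mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127
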