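"""Per-pixel water-content maps: apply a fitted model to every leaf pixel.

A feature extractor turns the (pixels x bands) matrix of leaf spectra into
the model's inputs — the NISDI scalar for the univariate index model, or
the reflectance at selected bands for multivariate models — and the model
predicts a water content per pixel.  Rendering maps low water content to
blue and high to red over a neutral background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image

from .cube import HyperCube
from .grid import WavelengthGrid
from .vindex import NISDI_REFL_NM, NISDI_SLOPE_NM, nisdi

__all__ = ["WaterMap", "nisdi_extractor", "band_extractor", "predict_map", "render_map"]


@dataclass
class WaterMap:
    """Per-pixel predicted water content; NaN off the leaf mask."""

    values: np.ndarray
    mask: np.ndarray
    model_id: str = "model"
    clip_range: tuple[float, float] = (0.0, 1.0)
    clipped_pixels: int = 0  # pixels outside clip_range (stored unclipped)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a shape")
        if np.isfinite(self.values[~self.mask]).any():
            raise ValueError("background pixels must be NaN")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("leaf pixels must all carry predictions")

    def masked_mean(self) -> float:
        return float(self.values[self.mask].mean())


def nisdi_extractor(grid: WavelengthGrid):
    """Extractor producing a one-column NISDI feature per pixel."""
    grid.require_cover(NISDI_SLOPE_NM, "NISDI slope anchor")
    grid.require_cover(NISDI_REFL_NM, "NISDI reflectance anchor")

    def extract(spectra: np.ndarray) -> np.ndarray:
        return np.asarray(nisdi(spectra, grid)).reshape(-1, 1)

    extract.feature_name = "NISDI"
    return extract


def band_extractor(grid: WavelengthGrid, band_indices: np.ndarray):
    """Extractor returning the reflectance at a fixed set of bands."""
    idx = np.asarray(band_indices, dtype=int)
    if idx.size == 0 or idx.min() < 0 or idx.max() >= len(grid):
        raise ValueError("band indices out of range for the grid")

    def extract(spectra: np.ndarray) -> np.ndarray:
        return np.asarray(spectra, dtype=float)[:, idx]

    extract.feature_name = f"bands[{idx.size}]"
    return extract


def predict_map(
    cube: HyperCube,
    model,
    feature_extractor,
    model_id: str = "model",
    clip_range: tuple[float, float] = (0.0, 1.0),
) -> WaterMap:
    """Predict water content for every leaf pixel of a cube."""
    if not cube.mask.any():
        raise ValueError("cube mask is empty: nothing to map")
    feats = feature_extractor(cube.leaf_pixels())
    pred = np.asarray(model.predict(feats), dtype=float).ravel()
    values = np.full(cube.mask.shape, np.nan)
    values[cube.mask] = pred
    lo, hi = clip_range
    clipped = int(((pred < lo) | (pred > hi)).sum())
    return WaterMap(values=values, mask=cube.mask, model_id=model_id, clip_range=clip_range, clipped_pixels=clipped)


def render_map(
    wmap: WaterMap,
    out_path,
    colormap: str = "jet",
    background_rgb: tuple[int, int, int] = (200, 200, 200),
) -> Path:
    """Render the map as a PNG: blue = dry, red = wet, neutral background.

    Values outside ``clip_range`` saturate at the end colors.  A sidecar
    JSON records the numeric color-scale bounds, and a gradient-strip PNG
    serves as the colorbar.  Output bytes are deterministic.
    """
    if not wmap.mask.any():
        raise ValueError("all-missing map: nothing to render")
    out_path = Path(out_path)
    lo, hi = wmap.clip_range
    if not hi > lo:
        raise ValueError("clip_range must have positive width")
    cmap = matplotlib.colormaps[colormap]
    norm = np.clip((wmap.values - lo) / (hi - lo), 0.0, 1.0)
    rgba = np.empty(wmap.values.shape + (3,), dtype=np.uint8)
    rgba[...] = background_rgb
    leaf_rgb = (cmap(norm[wmap.mask])[:, :3] * 255).round().astype(np.uint8)
    rgba[wmap.mask] = leaf_rgb
    Image.fromarray(rgba, mode="RGB").save(out_path)

    strip = (cmap(np.linspace(1, 0, 128))[:, None, :3] * 255).round().astype(np.uint8)
    strip = np.repeat(strip, 12, axis=1)
    Image.fromarray(strip, mode="RGB").save(out_path.with_name(out_path.stem + "_colorbar.png"))
    out_path.with_name(out_path.stem + "_scale.json").write_text(
        json.dumps({"model_id": wmap.model_id, "vmin": lo, "vmax": hi, "colormap": colormap}, indent=2)
    )
    return out_path
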