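"""Synthetic NIR leaf-reflectance generator.

The generator emulates the statistical structure that the estimation
pipeline assumes about real drying-series leaf data:

* 224-band reflectance spectra on a 900-1700 nm grid;
* Gaussian water-absorption troughs centred near 1440 nm (the strong O-H
  first-overtone feature) and 1190 nm, with depth proportional to the
  gravimetric water content, so reflectance rises as a leaf dries;
* per-spectrum multiplicative and additive scatter plus i.i.d. band noise,
  giving SNV/MSC preprocessing something real to remove;
* 4-step drying series per leaf group with geometric water loss;
* image cubes whose veins are wetter than the surrounding lamina and whose
  background is a distinct low-reflectance material.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import WavelengthGrid, default_grid

__all__ = [
    "SimConfig",
    "PlantedSignal",
    "VeinSpec",
    "DryingRecord",
    "SampleTable",
    "water_content",
    "noiseless_spectrum",
    "simulate_spectrum",
    "simulate_sample_table",
    "simulate_drying_series",
    "simulate_cube",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic spectral model.

    The reflectance model is a smooth continuum minus water absorption::

        R(lam; wc) = base(lam) - wc * (d_broad + sum_k d_k * N(lam; mu_k, s_k))

    followed by per-spectrum scatter ``(1 + e_m) * R + e_a`` and additive
    band noise.  ``base`` is a fixed low-order polynomial; absorption depth
    scales linearly with water content so the 1440 nm trough deepens as the
    leaf hydrates.
    """

    n_bands: int = 224
    grid_start_nm: float = 900.0
    grid_end_nm: float = 1700.0
    wc_range: tuple[float, float] = (0.14, 0.77)
    absorption_centers_nm: tuple[float, ...] = (1440.0, 1190.0)
    absorption_widths_nm: tuple[float, ...] = (80.0, 55.0)
    absorption_depth_per_wc: tuple[float, ...] = (0.55, 0.28)
    broadband_depth_per_wc: float = 0.12
    scatter_mult_sd: float = 0.05
    scatter_add_sd: float = 0.02
    # band noise of a *sample* spectrum: a leaf-region mean over thousands of
    # pixels, so i.i.d. pixel noise is largely averaged out
    noise_sd: float = 5e-4
    # band noise of a single cube pixel (line-scan NIR detector scale)
    pixel_noise_sd: float = 5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 4:
            raise ValueError("n_bands must be >= 4")
        if not self.grid_start_nm < self.grid_end_nm:
            raise ValueError("grid_start_nm must be < grid_end_nm")
        lo, hi = self.wc_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("wc_range must lie within [0, 1]")
        if len(self.absorption_centers_nm) != len(self.absorption_widths_nm) or len(
            self.absorption_centers_nm
        ) != len(self.absorption_depth_per_wc):
            raise ValueError("absorption center/width/depth lists must have equal length")
        for name in ("scatter_mult_sd", "scatter_add_sd", "noise_sd", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def grid(self) -> WavelengthGrid:
        return default_grid(self.n_bands, self.grid_start_nm, self.grid_end_nm)

    def without_noise(self) -> "SimConfig":
        return replace(self, scatter_mult_sd=0.0, scatter_add_sd=0.0, noise_sd=0.0)


@dataclass(frozen=True)
class PlantedSignal:
    """Exact affine band-pair signal: ``wc = alpha * (R_a - R_b) + beta``.

    Used to plant a known-best DVI pair into a sample table so that the
    exhaustive pair search has a ground truth to recover.
    """

    band_a: int
    band_b: int
    alpha: float = 2.0
    beta: float = 0.1

    def __post_init__(self) -> None:
        if self.band_a == self.band_b:
            raise ValueError("planted bands must differ")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")


@dataclass(frozen=True)
class VeinSpec:
    """Vein structure for synthetic cubes: veins are wetter than lamina."""

    wc_offset: float = 0.1
    n_side_veins: int = 3


@dataclass(frozen=True)
class DryingRecord:
    """One leaf group's drying series: masses G1..Gn, dry mass G0, water contents."""

    group_id: str
    masses_g: np.ndarray
    dry_mass_g: float
    water_contents: np.ndarray

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses_g, dtype=float)
        wc = np.asarray(self.water_contents, dtype=float)
        object.__setattr__(self, "masses_g", masses)
        object.__setattr__(self, "water_contents", wc)
        if self.dry_mass_g <= 0:
            raise ValueError("dry mass must be positive")
        if np.any(np.diff(masses) > 0) or masses[-1] < self.dry_mass_g:
            raise ValueError("masses must be non-increasing and >= dry mass")
        if np.any(np.diff(wc) > 1e-12):
            raise ValueError("water contents must be non-increasing")


@dataclass
class SampleTable:
    """Per-sample mean reflectance paired with gravimetric water content."""

    sample_ids: list[str]
    grid: WavelengthGrid
    reflectance: np.ndarray
    water_content: np.ndarray
    species: list[str]
    role: list[str]

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.water_content = np.asarray(self.water_content, dtype=float)
        n, p = self.reflectance.shape
        if len(self.water_content) != n or len(self.sample_ids) != n:
            raise ValueError("row counts of ids/reflectance/water_content must agree")
        if p != len(self.grid):
            raise ValueError("reflectance column count must equal grid length")
        if np.any((self.water_content < 0) | (self.water_content > 1)):
            raise ValueError("water contents must lie in [0, 1]")
        if len(self.species) != n or len(self.role) != n:
            raise ValueError("species/role must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    def subset(self, idx: np.ndarray) -> "SampleTable":
        idx = np.asarray(idx)
        return SampleTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            grid=self.grid,
            reflectance=self.reflectance[idx],
            water_content=self.water_content[idx],
            species=[self.species[i] for i in idx],
            role=[self.role[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "sample_id": self.sample_ids,
            "species": self.species,
            "role": self.role,
            "wc": self.water_content,
        }
        frame = pd.DataFrame(cols)
        bands = pd.DataFrame(
            self.reflectance, columns=[f"{w:.2f}" for w in self.grid.centers_nm]
        )
        return pd.concat([frame, bands.set_index(frame.index)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        frame = pd.read_csv(path)
        meta = ["sample_id", "species", "role", "wc"]
        band_cols = [c for c in frame.columns if c not in meta]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        return cls(
            sample_ids=[str(s) for s in frame["sample_id"]],
            grid=grid,
            reflectance=frame[band_cols].to_numpy(float),
            water_content=frame["wc"].to_numpy(float),
            species=[str(s) for s in frame["species"]],
            role=[str(s) for s in frame["role"]],
        )


def water_content(mass_g: float, dry_mass_g: float) -> float:
    """Gravimetric water content ``(G_n - G_0) / G_n`` as a fraction.

    ``G_n`` is the fresh (current) mass and ``G_0`` the oven-dry mass.
    """
    mass_g = float(mass_g)
    dry_mass_g = float(dry_mass_g)
    if dry_mass_g <= 0:
        raise ValueError("dry mass must be positive")
    if mass_g < dry_mass_g:
        raise ValueError("fresh mass cannot be below dry mass")
    return (mass_g - dry_mass_g) / mass_g


def _base_continuum(lam: np.ndarray, config: SimConfig) -> np.ndarray:
    # gentle upward continuum with slight curvature; wc-independent
    x = (lam - config.grid_start_nm) / (config.grid_end_nm - config.grid_start_nm)
    return 0.65 + 0.25 * x - 0.10 * x**2


def _absorption_profile(lam: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-band absorption depth per unit water content."""
    depth = np.full_like(lam, config.broadband_depth_per_wc, dtype=float)
    for mu, sig, d in zip(
        config.absorption_centers_nm,
        config.absorption_widths_nm,
        config.absorption_depth_per_wc,
    ):
        depth += d * np.exp(-0.5 * ((lam - mu) / sig) ** 2)
    return depth


def noiseless_spectrum(wc: float, config: SimConfig) -> np.ndarray:
    """Expected reflectance spectrum at water content ``wc`` (no scatter/noise)."""
    if not (0.0 <= wc <= 1.0):
        raise ValueError("water content must lie in [0, 1]")
    lam = config.grid.centers_nm
    r = _base_continuum(lam, config) - wc * _absorption_profile(lam, config)
    return np.clip(r, 0.0, None)


def simulate_spectrum(wc: float, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One noisy reflectance spectrum at water content ``wc``."""
    r = noiseless_spectrum(wc, config)
    e_mult = rng.normal(0.0, config.scatter_mult_sd) if config.scatter_mult_sd else 0.0
    e_add = rng.normal(0.0, config.scatter_add_sd) if config.scatter_add_sd else 0.0
    r = (1.0 + e_mult) * r + e_add
    if config.noise_sd:
        r = r + rng.normal(0.0, config.noise_sd, size=r.shape)
    return np.clip(r, 0.0, None)


def _scatter_and_noise(clean: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Vectorised scatter+noise for a (n, bands) matrix of clean spectra."""
    n = clean.shape[0]
    e_mult = rng.normal(0.0, config.scatter_mult_sd, size=(n, 1)) if config.scatter_mult_sd else 0.0
    e_add = rng.normal(0.0, config.scatter_add_sd, size=(n, 1)) if config.scatter_add_sd else 0.0
    out = (1.0 + e_mult) * clean + e_add
    if config.noise_sd:
        out = out + rng.normal(0.0, config.noise_sd, size=clean.shape)
    return np.clip(out, 0.0, None)


def simulate_sample_table(
    n_samples: int,
    config: SimConfig | None = None,
    planted: PlantedSignal | None = None,
    species: str = "peach",
    role: str = "calibration",
    seed: int | None = None,
) -> SampleTable:
    """Simulate a sample table with water contents uniform on ``wc_range``.

    With a :class:`PlantedSignal`, the spectra are post-edited so that
    ``wc = alpha * (R_a - R_b) + beta`` holds exactly, giving the band-pair
    search a known argmax with |r| = 1.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.wc_range
    if hi == lo and n_samples > 1:
        warnings.warn("degenerate wc_range: all samples share one water content")
    wc = rng.uniform(lo, hi, size=n_samples)
    clean = np.stack([noiseless_spectrum(w, config) for w in wc])
    refl = _scatter_and_noise(clean, config, rng)
    if planted is not None:
        # overwrite band a so the designated DVI reproduces wc exactly
        refl[:, planted.band_a] = refl[:, planted.band_b] + (wc - planted.beta) / planted.alpha
    return SampleTable(
        sample_ids=[f"{species}-{i:04d}" for i in range(n_samples)],
        grid=config.grid,
        reflectance=refl,
        water_content=wc,
        species=[species] * n_samples,
        role=[role] * n_samples,
    )


def planted_nisdi_table(
    n_samples: int,
    config: SimConfig | None = None,
    signal_fraction: float = 0.96,
    seed: int = 0,
) -> SampleTable:
    """Table whose water content is an affine function of NISDI plus noise.

    Spectra are generated as usual, their NISDI is computed, and the water
    content is replaced by ``affine(NISDI) + eps`` with ``var(eps)`` set so
    the signal accounts for ``signal_fraction`` of the wc variance.  A
    univariate NISDI regression on such a table should recover an R^2 near
    ``signal_fraction`` — a known-answer design for parameter recovery.
    """
    if not (0.0 < signal_fraction < 1.0):
        raise ValueError("signal_fraction must lie strictly in (0, 1)")
    from .vindex import nisdi  # lazy: vindex imports this module

    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    table = simulate_sample_table(n_samples, config, seed=int(rng.integers(2**31)))
    ni = np.asarray(nisdi(table.reflectance, table.grid))
    z = (ni - ni.mean()) / ni.std()
    lo, hi = config.wc_range
    signal_sd = (hi - lo) / 4.0
    signal = 0.5 * (lo + hi) + signal_sd * z
    noise_sd = signal_sd * np.sqrt((1.0 - signal_fraction) / signal_fraction)
    wc = signal + rng.normal(0.0, noise_sd, size=n_samples)
    n_out = int(((wc < 0) | (wc > 1)).sum())
    if n_out:
        warnings.warn(f"{n_out} planted water contents clipped into [0, 1]")
    table.water_content = np.clip(wc, 0.0, 1.0)
    return table


def simulate_drying_series(
    group_id: str,
    initial_wc: float,
    dry_mass_g: float,
    n_steps: int = 4,
    config: SimConfig | None = None,
    seed: int = 0,
    decay: float = 0.55,
) -> tuple[DryingRecord, np.ndarray]:
    """A drying series: n_steps mass/spectrum measurements of one leaf group.

    Water mass decays geometrically between steps (the oven protocol is not
    modelled physically).  Returns the record and a (n_steps, bands) matrix
    of per-step spectra.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not (0.0 < initial_wc < 1.0):
        raise ValueError("initial_wc must lie strictly in (0, 1)")
    if dry_mass_g <= 0:
        raise ValueError("dry mass must be positive")
    if not (0.0 < decay < 1.0):
        raise ValueError("decay must lie in (0, 1)")
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    water0 = dry_mass_g * initial_wc / (1.0 - initial_wc)  # invert wc = W/(W+G0)
    water = water0 * decay ** np.arange(n_steps)
    masses = dry_mass_g + water
    wcs = np.array([water_content(m, dry_mass_g) for m in masses])
    spectra = np.stack([simulate_spectrum(w, config, rng) for w in wcs])
    record = DryingRecord(group_id=group_id, masses_g=masses, dry_mass_g=dry_mass_g, water_contents=wcs)
    return record, spectra


def _leaf_geometry(height: int, width: int, vein_spec: VeinSpec) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical leaf mask plus a midrib-and-side-veins vein mask."""
    rr, cc = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    mask = ((rr - cy) / (0.45 * height)) ** 2 + ((cc - cx) / (0.38 * width)) ** 2 <= 1.0
    veins = np.zeros((height, width), dtype=bool)
    veins[:, int(round(cx))] = True  # midrib
    for k in range(1, vein_spec.n_side_veins + 1):
        r0 = int(round(cy + (k - (vein_spec.n_side_veins + 1) / 2.0) * height / (vein_spec.n_side_veins + 1)))
        for c in range(width):
            r = r0 + abs(c - int(round(cx))) // 3  # shallow diagonal branches
            if 0 <= r < height:
                veins[r, c] = True
    return mask, veins & mask


def simulate_cube(
    height: int,
    width: int,
    config: SimConfig | None = None,
    vein_spec: VeinSpec | None = None,
    seed: int = 0,
    base_wc: float | None = None,
) -> tuple["HyperCube", np.ndarray]:
    """Synthetic calibrated cube of one leaf with a known per-pixel wc map.

    Vein pixels' true water content exceeds the lamina by ``wc_offset``; the
    background is a distinct low-reflectance material.  Returns the cube
    (with its true leaf mask) and the ground-truth wc map (NaN off-leaf).
    """
    from .cube import HyperCube  # local import: cube module is format I/O

    if height < 8 or width < 8:
        raise ValueError("cube must be at least 8x8")
    config = config or SimConfig()
    vein_spec = vein_spec or VeinSpec()
    rng = np.random.default_rng(seed)
    mask, veins = _leaf_geometry(height, width, vein_spec)

    lo, hi = config.wc_range
    if base_wc is None:
        base_wc = 0.5 * (lo + hi)
    wc_map = np.full((height, width), np.nan)
    lamina_wc = base_wc + 0.03 * np.linspace(-1, 1, width)[None, :]  # mild tip-to-base gradient
    wc_map[mask] = np.broadcast_to(lamina_wc, (height, width))[mask]
    wc_map[veins] += vein_spec.wc_offset
    over = np.nan_to_num(wc_map) > 1.0
    if over.any():
        warnings.warn(f"vein offset pushed {int(over.sum())} pixels above wc=1; clipped")
        wc_map = np.where(over, 1.0, wc_map)

    n_bands = config.n_bands
    lam = config.grid.centers_nm
    pixel_config = replace(config, noise_sd=config.pixel_noise_sd)
    data = np.empty((height, width, n_bands))
    # background: flat dark material with small noise, no water absorption
    bg = ~mask
    data[bg] = np.clip(0.06 + rng.normal(0.0, 0.01, size=(int(bg.sum()), n_bands)), 0.0, None)
    leaf_wc = wc_map[mask]
    clean = _base_continuum(lam, config)[None, :] - leaf_wc[:, None] * _absorption_profile(lam, config)[None, :]
    data[mask] = _scatter_and_noise(np.clip(clean, 0.0, None), pixel_config, rng)
    cube = HyperCube(data=data, grid=config.grid, mask=mask)
    return cube, wc_map
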