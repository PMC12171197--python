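"""Vegetation indices for leaf water estimation.

The Near-Infrared Slope Difference Index (NISDI) combines the spectral
slope at 1559 nm with the reflectance in the strong 1440 nm O-H absorption
band::

    NISDI = 1.3e3 * D_1559 - 1.9 * R_1439

where D is the per-nm rate of change of reflectance (central difference on
interior bands) and R is reflectance.  The anchors snap to the nearest grid
band, since real instrument grids rarely contain the exact integers.

Alongside NISDI, the classical two-band families DVI = R_i - R_j,
RVI = R_i / R_j and NDVI = (R_i - R_j) / (R_i + R_j) are searched
exhaustively over all ordered band pairs, scoring each candidate by the
Pearson correlation of the index with water content (two-tailed t test).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import WavelengthGrid
from .synth import SampleTable

logger = logging.getLogger(__name__)

NISDI_SLOPE_NM = 1559.0
NISDI_REFL_NM = 1439.0
NISDI_SLOPE_COEF = 1.3e3
NISDI_REFL_COEF = 1.9

FAMILIES = ("DVI", "RVI", "NDVI")


@dataclass(frozen=True)
class SlopeSpectrum:
    grid: WavelengthGrid
    d_values: np.ndarray  # per-band slope, nm^-1


@dataclass(frozen=True)
class PairIndexDef:
    family: str
    band_i: int  # plays the NIR role
    band_j: int  # plays the Red role

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown index family '{self.family}'")
        if self.band_i == self.band_j:
            raise ValueError("pair bands must differ")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


@dataclass
class SearchResult:
    family: str
    heatmap: np.ndarray  # |r| over ordered pairs, NaN where undefined
    best_pair: PairIndexDef
    best_abs_r: float
    best_p: float

    def best_wavelengths_nm(self, grid: WavelengthGrid) -> tuple[float, float]:
        return (
            float(grid.centers_nm[self.best_pair.band_i]),
            float(grid.centers_nm[self.best_pair.band_j]),
        )


def slope(spectrum: np.ndarray, grid: WavelengthGrid) -> SlopeSpectrum:
    """Per-band reflectance slope in nm^-1.

    Central difference (R_{k+1} - R_{k-1}) / (lam_{k+1} - lam_{k-1}) on
    interior bands, one-sided at the ends.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] < 3:
        raise ValueError("slope needs at least 3 bands")
    return SlopeSpectrum(grid=grid, d_values=np.gradient(spectrum, grid.centers_nm, axis=-1))


def nisdi(spectrum: np.ndarray, grid: WavelengthGrid) -> float | np.ndarray:
    """NISDI of one spectrum (or row-wise of a matrix)."""
    i_d = grid.require_cover(NISDI_SLOPE_NM, "NISDI slope anchor")
    i_r = grid.require_cover(NISDI_REFL_NM, "NISDI reflectance anchor")
    spectrum = np.asarray(spectrum, dtype=float)
    d = slope(spectrum, grid).d_values
    out = NISDI_SLOPE_COEF * d[..., i_d] - NISDI_REFL_COEF * spectrum[..., i_r]
    return float(out) if out.ndim == 0 else out


def nisdi_table(table: SampleTable) -> np.ndarray:
    """NISDI value per sample of a table."""
    return np.asarray(nisdi(table.reflectance, table.grid))


def pair_index(family: str, r_i, r_j):
    """Two-band index value; undefined denominators become NaN."""
    if family not in FAMILIES:
        raise ValueError(f"unknown index family '{family}'")
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "DVI":
            out = r_i - r_j
        elif family == "RVI":
            out = np.where(r_j != 0, r_i / np.where(r_j == 0, 1.0, r_j), np.nan)
        else:  # NDVI
            s = r_i + r_j
            out = np.where(s != 0, (r_i - r_j) / np.where(s == 0, 1.0, s), np.nan)
    return float(out) if out.ndim == 0 else out


def pearson(x: np.ndarray, y: np.ndarray) -> PearsonResult:
    """Sample Pearson r with a two-tailed t-test p-value (n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("pearson needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.clip(xc @ yc / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return PearsonResult(r=r, p=p, n=n)


def _abs_corr_columns(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column of M against y, NaN-aware pairwise."""
    n, m = M.shape
    out = np.full(m, np.nan)
    finite = np.isfinite(M)
    full = finite.all(axis=0)
    if full.any():
        Mc = M[:, full] - M[:, full].mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((Mc**2).sum(axis=0) * float(yc @ yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[full] = np.abs(Mc.T @ yc) / denom
    for j in np.flatnonzero(~full):
        keep = finite[:, j]
        if keep.sum() < 3:
            continue
        mj = M[keep, j]
        yj = y[keep]
        if mj.std() == 0 or yj.std() == 0:
            continue
        out[j] = abs(np.corrcoef(mj, yj)[0, 1])
    return out


def search_pairs(table: SampleTable, family: str) -> SearchResult:
    """Exhaustive ordered band-pair search for one index family.

    Computes the index for every ordered pair (i, j), i != j, correlates it
    with water content and returns the full |r| heatmap plus the argmax
    pair (ties broken by lower i then lower j).  Samples with undefined
    index values (zero denominators) are dropped pairwise with a logged
    count.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown index family '{family}'")
    X = table.reflectance
    y = table.water_content
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 samples and 2 bands")
    if y.std() == 0:
        raise ValueError("water content is constant: correlation undefined")
    heat = np.full((p, p), np.nan)
    n_dropped = 0
    for i in range(p):
        M = pair_index(family, X[:, i : i + 1], X)
        n_dropped += int((~np.isfinite(M)).sum())
        row = _abs_corr_columns(M, y)
        row[i] = np.nan
        heat[i] = row
    if n_dropped:
        logger.info("%s search: %d undefined index values dropped pairwise", family, n_dropped)
    if not np.isfinite(heat).any():
        raise ValueError("no band pair yields a defined correlation")
    flat = np.nan_to_num(heat, nan=-1.0)
    bi, bj = np.unravel_index(int(np.argmax(flat)), heat.shape)  # C order = (lower i, lower j) ties
    idx = pair_index(family, X[:, bi], X[:, bj])
    keep = np.isfinite(idx)
    best = pearson(idx[keep], y[keep])
    return SearchResult(
        family=family,
        heatmap=heat,
        best_pair=PairIndexDef(family, int(bi), int(bj)),
        best_abs_r=float(abs(best.r)),
        best_p=best.p,
    )


@dataclass
class IndexModel:
    """Univariate linear model wc ~ slope * index + intercept."""

    slope: float
    intercept: float
    n_wavelengths: int = 2

    def predict(self, index_values: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(index_values, dtype=float) + self.intercept


def fit_index_model(
    index_values: np.ndarray,
    wc: np.ndarray,
    pred_index: np.ndarray | None = None,
    pred_wc: np.ndarray | None = None,
    n_wavelengths: int = 2,
):
    """Ordinary least squares of water content on one index.

    Returns (model, metrics): calibration R^2/RMSE always; prediction-set
    R_P^2/RMSEP when a prediction set is supplied.
    """
    from .regress import FitMetrics, evaluate_arrays

    x = np.asarray(index_values, dtype=float)
    y = np.asarray(wc, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0:
        raise ValueError("zero-variance index: cannot fit")
    b, a = np.polyfit(x, y, 1)
    model = IndexModel(slope=float(b), intercept=float(a), n_wavelengths=n_wavelengths)
    r2_cal, rmse_cal = evaluate_arrays(y, model.predict(x))
    metrics = FitMetrics(r2_cal=r2_cal, rmse_cal=rmse_cal)
    if pred_index is not None and pred_wc is not None:
        r2_p, rmsep = evaluate_arrays(np.asarray(pred_wc, float), model.predict(pred_index))
        metrics.r2_pred = r2_p
        metrics.rmsep = rmsep
    return model, metrics
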