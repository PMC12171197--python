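"""Spectral preprocessing and the PLSR harness that ranks the methods.

The suite covers the nine standard chemometric treatments — Savitzky-Golay
smoothing (SG), per-spectrum min-max normalisation (Nor), standard normal
variate (SNV), multiplicative scatter correction (MSC), first derivative
(FD), and the four SG+X combinations — applied row-wise to a samples x
bands reflectance matrix.  ``compare_preprocessing`` fits a PLSR model per
method, choosing the component count by 10-fold cross-validation, and ranks
the methods by RMSECV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from ._pls import fit_pls, plsr_component_cv
from .grid import WavelengthGrid
from .synth import SampleTable

PREP_NAMES = ("none", "SG", "Nor", "SNV", "MSC", "FD", "SG+Nor", "SG+SNV", "SG+MSC", "SG+FD")


@dataclass(frozen=True)
class PrepMethod:
    """One named preprocessing treatment; SG defaults are window 11, order 2."""

    name: str = "none"
    sg_window: int = 11
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.name not in PREP_NAMES:
            raise ValueError(f"unknown preprocessing '{self.name}'; choose from {PREP_NAMES}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")

    def apply(self, X: np.ndarray, grid: WavelengthGrid, reference: np.ndarray | None = None) -> np.ndarray:
        steps = self.name.split("+") if self.name != "none" else []
        out = np.asarray(X, dtype=float)
        for step in steps:
            if step == "SG":
                out = savitzky_golay(out, self.sg_window, self.sg_polyorder, grid=grid)
            elif step == "Nor":
                out = normalize(out)
            elif step == "SNV":
                out = snv(out)
            elif step == "MSC":
                out = msc(out, reference=reference)
            elif step == "FD":
                out = first_derivative(out, grid)
        return out


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[None, :] if X.ndim == 1 else X


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row centred and scaled to sd 1 (n-1)."""
    X = _as_matrix(X)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        rows = np.flatnonzero(sd == 0)
        raise ValueError(f"constant rows cannot be SNV-scaled: {rows.tolist()}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as ``x ~ a + b * reference`` by least squares and
    replaced by ``(x - a) / b``.  The reference defaults to the column mean
    of X; pass the calibration-set mean when transforming held-out sets.
    """
    X = _as_matrix(X)
    if X.shape[1] < 2:
        raise ValueError("MSC needs at least 2 bands")
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("constant reference spectrum")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12):
        rows = np.flatnonzero(np.abs(b) < 1e-12)
        raise ValueError(f"MSC slope ~ 0 for rows {rows.tolist()}")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def savitzky_golay(
    X: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
    deriv_order: int = 0,
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """Savitzky-Golay filtering along bands; derivatives are per-nm.

    Edges use a polynomial fitted to the outermost full window, so every
    band (including those feeding index extraction) stays defined.
    """
    X = _as_matrix(X)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > X.shape[1]:
        raise ValueError("window exceeds the band count")
    if deriv_order > polyorder:
        raise ValueError("deriv_order cannot exceed polyorder")
    delta = grid.mean_spacing_nm if grid is not None else 1.0
    return savgol_filter(X, window, polyorder, deriv=deriv_order, delta=delta, axis=1, mode="interp")


def normalize(X: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Per-row min-max normalisation to [0, 1]."""
    if mode != "minmax":
        raise ValueError(f"unknown normalisation mode '{mode}'")
    X = _as_matrix(X)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        rows = np.flatnonzero(span.ravel() == 0)
        raise ValueError(f"constant rows cannot be min-max scaled: {rows.tolist()}")
    return (X - lo) / span


def first_derivative(X: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    """Finite-difference dR/dlambda in nm^-1: central interior, one-sided ends."""
    X = _as_matrix(X)
    if X.shape[1] < 2:
        raise ValueError("first derivative needs at least 2 bands")
    return np.gradient(X, grid.centers_nm, axis=1)


def compare_preprocessing(
    table: SampleTable,
    methods: list[PrepMethod] | None = None,
    max_components: int = 10,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank preprocessing methods by PLSR 10-fold RMSECV.

    For each method the matrix is transformed, a PLSR component count in
    1..max_components is chosen by minimum 10-fold RMSECV, and calibration
    R^2/RMSE plus cross-validated R_cv^2/RMSECV are reported.  Fold
    assignment depends only on (n, k, seed).
    """
    if methods is None:
        methods = [PrepMethod(name) for name in PREP_NAMES]
    y = table.water_content
    n = table.n_samples
    if k > n:
        raise ValueError("k cannot exceed the sample count")
    rows = []
    for method in methods:
        Xp = method.apply(table.reflectance, table.grid)
        best_a, rmsecv, oof = plsr_component_cv(Xp, y, max_components, k, seed)
        pls = fit_pls(Xp, y, best_a)
        pred = pls.predict(Xp).ravel()
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        rows.append(
            {
                "method": method.name,
                "n_components": best_a,
                "r2_cal": 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot,
                "rmse_cal": float(np.sqrt(np.mean((y - pred) ** 2))),
                "r2_cv": 1.0 - float(np.sum((y - oof) ** 2)) / ss_tot,
                "rmsecv": float(rmsecv[best_a - 1]),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values("rmsecv", kind="stable").reset_index(drop=True)
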