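"""Characteristic-wavelength selection: CARS, SPA and UVE.

All three selectors take a (samples x bands) matrix and the water-content
vector and return a :class:`SelectionResult` — the chosen band subset plus
the RMSE/RMSECV trace that justified it.

* CARS (competitive adaptive reweighted sampling): Monte-Carlo PLS runs on
  random sample subsets; at each iteration an exponentially decreasing
  retention schedule fixes how many bands survive, and competitive
  reweighted sampling (probability proportional to |PLS coefficient|)
  decides which.  The subset with minimum 10-fold RMSECV wins.
* SPA (successive projections algorithm): forward chains that repeatedly
  add the band with the largest projection onto the orthogonal complement
  of those already chosen, minimising collinearity; candidate set sizes are
  scored by MLR RMSE on a held-out split.
* UVE (uninformative variable elimination): appends tiny random noise
  bands, measures each coefficient's stability mean/sd under resampling,
  and eliminates real bands whose stability does not beat the noise bands'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._pls import fit_pls, max_usable_components, plsr_component_cv
from .grid import WavelengthGrid

__all__ = ["SelectionResult", "cars", "spa", "uve"]


@dataclass
class SelectionResult:
    method: str
    selected_band_indices: np.ndarray
    selected_wavelengths_nm: np.ndarray
    trace: np.ndarray
    best_trace_value: float
    settings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_band_indices, dtype=int)
        if idx.size < 1 or len(np.unique(idx)) != idx.size:
            raise ValueError("selected indices must be unique and non-empty")
        object.__setattr__(self, "selected_band_indices", np.sort(idx))

    @property
    def n_selected(self) -> int:
        return int(self.selected_band_indices.size)


def _wavelengths(grid: WavelengthGrid | None, idx: np.ndarray, p: int) -> np.ndarray:
    if grid is None:
        return np.asarray(idx, dtype=float)
    if len(grid) != p:
        raise ValueError("grid length must match the band count")
    return grid.centers_nm[idx]


def _edf_schedule(p: int, n_mc: int) -> np.ndarray:
    """Exponentially decreasing retained-band counts: p at step 1, 2 at step n_mc."""
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    k = np.log(p / 2.0) / (n_mc - 1)
    ratios = np.exp(k) * np.exp(-k * np.arange(1, n_mc + 1))
    return np.clip(np.round(p * ratios).astype(int), 2, p)


def cars(
    X: np.ndarray,
    y: np.ndarray,
    n_mc: int = 50,
    k_folds: int = 10,
    sample_fraction: float = 0.8,
    max_pls_components: int = 10,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling wavelength selection."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < k_folds:
        raise ValueError("need at least k_folds samples")
    if p < 2:
        raise ValueError("need at least 2 bands")
    rng = np.random.default_rng(seed)
    schedule = _edf_schedule(p, n_mc)
    retained = np.arange(p)
    subsets: list[np.ndarray] = []
    rmsecv = np.empty(n_mc)
    warned_clamp = False
    for i in range(n_mc):
        sub = rng.choice(n, size=max(k_folds, int(round(sample_fraction * n))), replace=False)
        a = max_usable_components(sub.size, retained.size, max_pls_components)
        if retained.size < max_pls_components and retained.size < p and not warned_clamp:
            warnings.warn(
                f"CARS iteration {i + 1}: {retained.size} surviving bands; "
                f"PLS components clamped to {a} (and further as bands drop)"
            )
            warned_clamp = True
        pls = fit_pls(X[np.ix_(sub, retained)], y[sub], a)
        w = np.abs(pls.coef_.ravel())
        n_keep = min(schedule[i], retained.size)
        # competitive reweighted sampling: draw exactly n_keep survivors
        # without replacement, probability proportional to |coefficient|
        w = w + 1e-12
        keep = rng.choice(retained.size, size=n_keep, replace=False, p=w / w.sum())
        retained = np.sort(retained[keep])
        _, trace_a, _ = plsr_component_cv(X[:, retained], y, max_pls_components, k_folds, seed)
        rmsecv[i] = trace_a.min()
        subsets.append(retained.copy())
    best = int(np.argmin(rmsecv))
    sel = subsets[best]
    return SelectionResult(
        method="CARS",
        selected_band_indices=sel,
        selected_wavelengths_nm=_wavelengths(grid, np.sort(sel), p),
        trace=rmsecv,
        best_trace_value=float(rmsecv[best]),
        settings={
            "n_mc": n_mc,
            "k_folds": k_folds,
            "sample_fraction": sample_fraction,
            "max_pls_components": max_pls_components,
            "best_iteration": best + 1,
            "retained_counts": [int(s.size) for s in subsets],
        },
        seed=seed,
    )


def spa(
    X: np.ndarray,
    y: np.ndarray,
    max_vars: int = 30,
    min_vars: int = 2,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
    val_fraction: float = 1.0 / 3.0,
) -> SelectionResult:
    """Successive projections algorithm wavelength selection.

    Each starting band seeds a projection chain; candidate (start, size)
    combinations are scored by MLR RMSE on a seeded 2/3-1/3 split and the
    minimum wins.  The trace is the best RMSE per variable count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not (1 <= min_vars <= max_vars):
        raise ValueError("need 1 <= min_vars <= max_vars")
    if max_vars > min(n - 1, p):
        raise ValueError("max_vars cannot exceed min(n - 1, p)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val, train = perm[:n_val], perm[n_val:]
    if train.size <= max_vars:
        raise ValueError("training split too small for max_vars")

    col_norm0 = np.linalg.norm(X, axis=0)
    chains: list[list[int]] = []
    for start in range(p):
        P = X.copy()
        chain = [start]
        for _ in range(max_vars - 1):
            v = P[:, chain[-1]]
            vv = float(v @ v)
            if vv < 1e-24:
                warnings.warn(f"SPA chain from band {start} truncated: rank deficient")
                break
            P = P - np.outer(v, v @ P) / vv
            norms = np.linalg.norm(P, axis=0)
            norms[chain] = -1.0
            nxt = int(np.argmax(norms))
            if norms[nxt] <= 1e-10 * max(col_norm0[nxt], 1.0):
                warnings.warn(f"SPA chain from band {start} truncated: rank deficient")
                break
            chain.append(nxt)
        chains.append(chain)

    counts = np.arange(min_vars, max_vars + 1)
    trace = np.full(counts.size, np.inf)
    best = (np.inf, 0, min_vars)  # (rmse, start, size)
    Xtr, ytr, Xva, yva = X[train], y[train], X[val], y[val]
    for start, chain in enumerate(chains):
        for m in range(min_vars, len(chain) + 1):
            cols = chain[:m]
            design = np.column_stack([np.ones(train.size), Xtr[:, cols]])
            beta, *_ = np.linalg.lstsq(design, ytr, rcond=None)
            pred = beta[0] + Xva[:, cols] @ beta[1:]
            rmse = float(np.sqrt(np.mean((yva - pred) ** 2)))
            ci = m - min_vars
            if rmse < trace[ci]:
                trace[ci] = rmse
            if rmse < best[0]:
                best = (rmse, start, m)
    sel = np.array(chains[best[1]][: best[2]], dtype=int)
    return SelectionResult(
        method="SPA",
        selected_band_indices=sel,
        selected_wavelengths_nm=_wavelengths(grid, np.sort(sel), p),
        trace=trace,
        best_trace_value=float(best[0]),
        settings={"max_vars": max_vars, "min_vars": min_vars, "start_band": best[1], "counts": counts.tolist()},
        seed=seed,
    )


def uve(
    X: np.ndarray,
    y: np.ndarray,
    n_noise: int | None = None,
    noise_scale: float = 1e-10,
    max_pls_components: int = 10,
    cutoff_factor: float = 1.0,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
) -> SelectionResult:
    """Uninformative variable elimination wavelength selection.

    Coefficient stability is mean/sd of the PLS coefficient under
    leave-one-out resampling (n <= 200) or 100 Monte-Carlo leave-10%-out
    rounds; real bands whose |stability| does not exceed
    ``cutoff_factor x max |stability of noise bands|`` are eliminated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("UVE needs at least 10 samples")
    n_noise = p if n_noise is None else int(n_noise)
    rng = np.random.default_rng(seed)
    noise = rng.uniform(0.0, 1.0, size=(n, n_noise)) * noise_scale
    Z = np.column_stack([X, noise])

    a, _, _ = plsr_component_cv(X, y, max_pls_components, k=min(10, n), seed=seed)
    if n <= 200:
        rounds = [np.setdiff1d(np.arange(n), [i]) for i in range(n)]
    else:
        n_out = max(1, int(round(0.1 * n)))
        rounds = [
            np.setdiff1d(np.arange(n), rng.choice(n, size=n_out, replace=False))
            for _ in range(100)
        ]
    coefs = np.empty((len(rounds), p + n_noise))
    for r, keep in enumerate(rounds):
        pls = fit_pls(Z[keep], y[keep], a)
        coefs[r] = pls.coef_.ravel()
    sd = coefs.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    stability = coefs.mean(axis=0) / sd
    cutoff = cutoff_factor * np.abs(stability[p:]).max()
    real = np.abs(stability[:p])
    retained = np.flatnonzero(real > cutoff)
    if retained.size == 0:
        raise ValueError(
            "no band exceeds the noise stability cutoff; try a smaller cutoff_factor"
        )
    order = retained[np.argsort(-real[retained], kind="stable")]
    trace = np.empty(order.size)
    for m in range(1, order.size + 1):
        _, rm, _ = plsr_component_cv(X[:, np.sort(order[:m])], y, max_pls_components, min(10, n), seed)
        trace[m - 1] = rm.min()
    best_m = int(np.argmin(trace)) + 1
    sel = np.sort(order[:best_m])
    return SelectionResult(
        method="UVE",
        selected_band_indices=sel,
        selected_wavelengths_nm=_wavelengths(grid, sel, p),
        trace=trace,
        best_trace_value=float(trace[best_m - 1]),
        settings={
            "n_noise": n_noise,
            "noise_scale": noise_scale,
            "cutoff_factor": cutoff_factor,
            "n_components": a,
            "n_retained_by_cutoff": int(retained.size),
        },
        seed=seed,
    )
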