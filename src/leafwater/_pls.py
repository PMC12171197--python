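"""PLS1 utilities shared by the preprocessing harness and wavelength selectors.

One sklearn PLS fit with A components yields the regression vectors of all
nested sub-models 1..A (B_a = W_a (P_a' W_a)^{-1} q_a on centred data), so
10-fold RMSECV over component counts costs one fit per fold rather than one
per (fold, count).
"""

from __future__ import annotations

import numpy as np
from sklearn.cross_decomposition import PLSRegression


def max_usable_components(n_train: int, p: int, cap: int) -> int:
    return max(1, min(cap, p, n_train - 1))


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    n_components = max_usable_components(X.shape[0], X.shape[1], n_components)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y.reshape(-1, 1))
    return pls


def coefficient_paths(pls: PLSRegression) -> list[tuple[float, np.ndarray]]:
    """(intercept, coef) of every nested sub-model of a fitted PLS1 model."""
    W = pls.x_weights_
    P = pls.x_loadings_
    q = pls.y_loadings_.ravel()
    x_mean = pls._x_mean
    y_mean = float(np.ravel(pls._y_mean)[0])
    out = []
    for a in range(1, W.shape[1] + 1):
        R = W[:, :a] @ np.linalg.pinv(P[:, :a].T @ W[:, :a])
        coef = R @ q[:a]
        out.append((y_mean - float(x_mean @ coef), coef))
    return out


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic fold assignment depending only on (n, k, seed)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k cannot exceed the sample count")
    perm = np.random.default_rng(seed).permutation(n)
    return [perm[i::k] for i in range(k)]


def plsr_component_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    k: int = 10,
    seed: int = 0,
) -> tuple[int, np.ndarray, np.ndarray]:
    """10-fold RMSECV over PLS component counts 1..A.

    Returns (best count, RMSECV per count, pooled out-of-fold predictions of
    the best count).
    """
    n, p = X.shape
    folds = kfold_indices(n, k, seed)
    a_max = max_usable_components(n - max(len(f) for f in folds), p, max_components)
    oof = np.zeros((a_max, n))
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        pls = fit_pls(X[train], y[train], a_max)
        for a, (b0, coef) in enumerate(coefficient_paths(pls)):
            oof[a, test_idx] = b0 + X[test_idx] @ coef
    rmsecv = np.sqrt(np.mean((oof - y[None, :]) ** 2, axis=1))
    best = int(np.argmin(rmsecv))
    return best + 1, rmsecv, oof[best]
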