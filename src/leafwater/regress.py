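"""Dataset splitting, the four regression back-ends, CV and metrics.

The back-ends mirror the standard chemometric line-up: PLSR (7 latent
variables by default for characteristic-wavelength models), MLR, random
forest (100 trees, seed 42) and a ReLU multilayer perceptron (4 hidden
layers, 1000 optimizer iterations).  Metrics are R^2 and RMSE on the
calibration set, pooled 10-fold cross-validation (R_cv^2, RMSECV) and the
held-out prediction set (R_P^2, RMSEP); prediction-set R^2 uses the
prediction-set mean in SS_tot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from ._pls import kfold_indices, max_usable_components
from .synth import SampleTable

__all__ = ["FitMetrics", "RegressorSpec", "split", "fit", "kfold_cv", "evaluate", "evaluate_arrays"]


@dataclass
class FitMetrics:
    r2_cal: float | None = None
    rmse_cal: float | None = None
    r2_cv: float | None = None
    rmsecv: float | None = None
    r2_pred: float | None = None
    rmsep: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass(frozen=True)
class RegressorSpec:
    """Which back-end to fit and its (mostly conventional) hyperparameters."""

    kind: Literal["PLSR", "MLR", "RF", "ANN"] = "PLSR"
    n_components: int = 7
    n_trees: int = 100
    rf_seed: int = 42
    ann_hidden_layers: tuple[int, ...] = (64, 32, 16, 8)
    ann_iterations: int = 1000
    ann_seed: int = 0
    mlr_min_norm: bool = False  # pseudo-inverse fit for singular designs

    def __post_init__(self) -> None:
        if self.kind not in ("PLSR", "MLR", "RF", "ANN"):
            raise ValueError(f"unknown regressor kind '{self.kind}'")
        for name in ("n_components", "n_trees", "ann_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


class _MLR:
    """Least-squares linear model with an explicit collinearity check.

    With ``min_norm=True`` a rank-deficient design is fitted by the
    minimum-norm least-squares solution instead of raising.  Row-normalised
    spectra need this: SNV forces every spectrum to zero mean, so the full
    band set carries an exact linear dependency.
    """

    def __init__(self, min_norm: bool = False):
        self.min_norm = min_norm

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MLR":
        n, p = X.shape
        if n <= p and not self.min_norm:
            raise ValueError(f"MLR needs more samples ({n}) than parameters ({p + 1})")
        design = np.column_stack([np.ones(n), X])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1] and not self.min_norm:
            # name a dependent column: first one whose addition does not raise rank
            r = 1
            for j in range(1, design.shape[1]):
                rj = np.linalg.matrix_rank(design[:, : j + 1])
                if rj == r:
                    raise ValueError(f"singular design: column {j - 1} is collinear with earlier columns")
                r = rj
            raise ValueError("singular design matrix")
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept_ + np.asarray(X, float) @ self.coef_


class _PLSWrap:
    """PLSRegression returning flat prediction vectors."""

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X, y):
        a = max_usable_components(X.shape[0], X.shape[1], self.n_components)
        self._pls = PLSRegression(n_components=a, scale=False).fit(X, y.reshape(-1, 1))
        return self

    def predict(self, X):
        return self._pls.predict(X).ravel()


class _SkWrap:
    def __init__(self, est):
        self._est = est

    def fit(self, X, y):
        self._est.fit(X, y)
        return self

    def predict(self, X):
        return np.asarray(self._est.predict(X), float).ravel()


def split(
    table: SampleTable,
    test_fraction: float = 0.3,
    method: str = "random",
    seed: int = 0,
    n_strata: int = 5,
) -> tuple[SampleTable, SampleTable]:
    """Disjoint, exhaustive calibration/prediction partition.

    ``method='stratified'`` balances the water-content distribution across
    the two sets by sampling within wc quantile bins.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    n = table.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    if method == "random":
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
    elif method == "stratified":
        qs = np.quantile(table.water_content, np.linspace(0, 1, n_strata + 1)[1:-1])
        bins = np.digitize(table.water_content, qs)
        picks = []
        for b in np.unique(bins):
            members = rng.permutation(np.flatnonzero(bins == b))
            picks.append(members[: int(round(len(members) * test_fraction))])
        test_idx = np.sort(np.concatenate(picks)) if picks else np.array([], int)
    else:
        raise ValueError(f"unknown split method '{method}'")
    cal_idx = np.setdiff1d(np.arange(n), test_idx)
    cal, pred = table.subset(cal_idx), table.subset(test_idx)
    pred.role = ["prediction"] * pred.n_samples
    return cal, pred


def fit(spec: RegressorSpec, X: np.ndarray, y: np.ndarray):
    """Fit the requested back-end; the result exposes ``predict``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if spec.kind == "MLR":
        return _MLR(min_norm=spec.mlr_min_norm).fit(X, y)
    if spec.kind == "PLSR":
        return _PLSWrap(spec.n_components).fit(X, y)
    if spec.kind == "RF":
        est = RandomForestRegressor(n_estimators=spec.n_trees, random_state=spec.rf_seed)
        return _SkWrap(est).fit(X, y)
    # ANN: ReLU MLP, full ann_iterations (convergence-based stopping disabled);
    # inputs standardised inside the pipeline for optimiser stability
    mlp = MLPRegressor(
        hidden_layer_sizes=spec.ann_hidden_layers,
        activation="relu",
        max_iter=spec.ann_iterations,
        random_state=spec.ann_seed,
        tol=0.0,
        n_iter_no_change=spec.ann_iterations,
    )
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning

    pipe = make_pipeline(StandardScaler(), mlp)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        return _SkWrap(pipe).fit(X, y)


def kfold_cv(spec: RegressorSpec, X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0) -> FitMetrics:
    """Pooled out-of-fold metrics: RMSECV and R_cv^2 over all samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    folds = kfold_indices(n, k, seed)
    oof = np.empty(n)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        model = fit(spec, X[train], y[train])
        oof[test_idx] = model.predict(X[test_idx])
    r2, rmse = evaluate_arrays(y, oof)
    return FitMetrics(r2_cv=r2, rmsecv=rmse)


def evaluate_arrays(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(R^2, RMSE) with SS_tot about the evaluation-set mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty evaluation set")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance target: R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot, float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def evaluate(model, X: np.ndarray, y: np.ndarray) -> FitMetrics:
    """R^2 and RMSE of a fitted model on an evaluation set."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    r2, rmse = evaluate_arrays(y, model.predict(X))
    return FitMetrics(r2_cal=r2, rmse_cal=rmse)
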