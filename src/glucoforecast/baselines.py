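"""The five comparison forecasters: feed-forward ANN, k-nearest-neighbors
regression, ridge regression, Gaussian kernel ridge regression, and a
last-n-days moving average.

Every ML baseline consumes exactly the same supervised windows as the LSTM
(flattened to ``lookback * 6`` feature vectors, scaled), and returns scaled
predictions, so comparisons are apples-to-apples.  The moving average ignores
covariates by construction: its prediction for day t is the mean of the last
``window_n`` observed glucose values before t (shortened when fewer exist).

Ridge and kernel-ridge penalties (and the kernel bandwidth) are tuned on the
validation split by grid search; KNN's k defaults to 3 and the moving-average
window to 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor

from glucoforecast.cohort import PatientSeries
from glucoforecast.preprocess import WindowedDataset


@dataclass
class BaselineConfig:
    """Settings for one baseline method."""

    method: str  # ann | knn | ridge | kernel_ridge | moving_average
    k: int = 3
    window_n: int = 3
    penalty: float | None = None  # ridge / kernel ridge lambda; None -> tune
    bandwidth: float | None = None  # kernel ridge gamma; None -> tune
    hidden_sizes: tuple[int, ...] = (16,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("ann", "knn", "ridge", "kernel_ridge", "moving_average"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.k < 1 or self.window_n < 1:
            raise ValueError("k and window_n must be >= 1")
        if self.penalty is not None and self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.method == "ann" and any(h < 1 for h in self.hidden_sizes):
            raise ValueError("ann hidden layer sizes must be >= 1")


def _flat(ds: WindowedDataset) -> np.ndarray:
    return ds.inputs.reshape(len(ds), -1)


def moving_average_predict(history: np.ndarray, window_n: int = 3) -> float:
    """Mean of the last ``window_n`` values of an observed glucose history;
    mean of whatever exists when fewer are available."""
    h = np.asarray(history, dtype=float)
    if h.size == 0:
        raise ValueError("empty glucose history")
    return float(h[-window_n:].mean())


def moving_average_series(
    series: PatientSeries, target_days: np.ndarray, window_n: int = 3
) -> np.ndarray:
    """Moving-average forecasts (mg/dL) for the given target day indices,
    using only glucose values *observed* strictly before each target day."""
    g = series.values["glucose_mgdl"].to_numpy()
    obs = series.observed["glucose_mgdl"].to_numpy()
    preds = np.empty(len(target_days))
    for i, t in enumerate(np.asarray(target_days, dtype=int)):
        hist = g[:t][obs[:t]]
        if hist.size == 0:  # nothing observed yet: fall back to imputed values
            hist = g[:t]
        preds[i] = moving_average_predict(hist, window_n)
    return preds


def knn_predict(train_X: np.ndarray, train_y: np.ndarray, query: np.ndarray,
                k: int = 3) -> np.ndarray:
    """Unweighted k-nearest-neighbor mean on Euclidean distance.

    Equal distances resolve to the earlier training index, which corresponds
    to the earlier day since windows are chronological.
    """
    train_X = np.atleast_2d(train_X)
    if k > len(train_X):
        raise ValueError(f"k ({k}) exceeds number of training points ({len(train_X)})")
    model = KNeighborsRegressor(n_neighbors=k, weights="uniform", algorithm="brute")
    model.fit(train_X, train_y)
    return model.predict(np.atleast_2d(query))


def ridge_fit(X: np.ndarray, y: np.ndarray, penalty: float,
              fit_intercept: bool = True):
    """Ridge regression with unpenalized intercept (via centering)."""
    if penalty == 0:
        model = LinearRegression(fit_intercept=fit_intercept)
    else:
        model = Ridge(alpha=penalty, fit_intercept=fit_intercept)
    model.fit(np.atleast_2d(X), y)
    return model


def kernel_ridge_fit(X: np.ndarray, y: np.ndarray, penalty: float, bandwidth: float):
    """Kernel ridge with Gaussian kernel k(a,b) = exp(-gamma * ||a-b||^2)."""
    model = KernelRidge(alpha=penalty, kernel="rbf", gamma=bandwidth)
    model.fit(np.atleast_2d(X), y)
    return model


def ann_train(
    data: WindowedDataset,
    val: WindowedDataset,
    hidden_sizes: tuple[int, ...] = (16,),
    seed: int = 0,
    epochs: int = 200,
    learning_rate: float = 1e-3,
) -> MLPRegressor:
    """Feed-forward net on flattened windows; epoch with best validation RMSE
    wins (tracked manually through ``partial_fit``)."""
    if len(data) == 0:
        raise ValueError("empty training dataset")
    X, y = _flat(data), data.targets
    model = MLPRegressor(
        hidden_layer_sizes=hidden_sizes,
        solver="adam",
        learning_rate_init=learning_rate,
        random_state=seed,
        max_iter=1,
        warm_start=False,
    )
    best_state, best_rmse = None, np.inf
    for _ in range(epochs):
        model.partial_fit(X, y)
        if len(val) > 0:
            pred = model.predict(_flat(val))
            rmse = float(np.sqrt(np.mean((pred - val.targets) ** 2)))
        else:
            pred = model.predict(X)
            rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        if rmse < best_rmse:
            best_rmse = rmse
            best_state = ([w.copy() for w in model.coefs_],
                          [b.copy() for b in model.intercepts_])
    assert best_state is not None
    model.coefs_, model.intercepts_ = best_state
    return model


# ---------------------------------------------------------------------------
# Uniform predictor interface used by evaluation.compare_methods.
# ---------------------------------------------------------------------------

@dataclass
class BaselinePredictor:
    """fit/predict wrapper giving every baseline the same surface."""

    config: BaselineConfig
    _model: object = field(default=None, repr=False)
    _series: PatientSeries | None = field(default=None, repr=False)

    def fit(self, train: WindowedDataset, val: WindowedDataset,
            series: PatientSeries | None = None) -> "BaselinePredictor":
        cfg = self.config
        if cfg.method == "moving_average":
            if series is None:
                raise ValueError("moving_average needs the patient series")
            self._series = series
            return self
        X, y = _flat(train), train.targets
        if cfg.method == "knn":
            k = min(cfg.k, len(X))
            self._model = KNeighborsRegressor(n_neighbors=k, weights="uniform",
                                              algorithm="brute").fit(X, y)
        elif cfg.method == "ridge":
            lam = cfg.penalty
            if lam is None:
                lam = _tune_ridge(X, y, val)
            self._model = ridge_fit(X, y, lam)
        elif cfg.method == "kernel_ridge":
            lam, gam = cfg.penalty, cfg.bandwidth
            if lam is None or gam is None:
                lam, gam = _tune_kernel_ridge(X, y, val, lam, gam)
            self._model = kernel_ridge_fit(X, y, lam, gam)
        elif cfg.method == "ann":
            self._model = ann_train(train, val, cfg.hidden_sizes, cfg.seed)
        return self

    def predict(self, test: WindowedDataset) -> np.ndarray:
        """Scaled predictions for the test windows (mg/dL for moving_average,
        which bypasses scaling; callers inverse-scale the others)."""
        if self.config.method == "moving_average":
            assert self._series is not None
            return moving_average_series(self._series, test.day_indices,
                                         self.config.window_n)
        assert self._model is not None
        return np.asarray(self._model.predict(_flat(test)), dtype=float)


def _val_rmse(model, val: WindowedDataset) -> float:
    pred = model.predict(_flat(val))
    return float(np.sqrt(np.mean((pred - val.targets) ** 2)))


def _tune_ridge(X, y, val: WindowedDataset) -> float:
    grid = [1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0]
    if len(val) == 0:
        return 1.0
    scores = [(_val_rmse(ridge_fit(X, y, lam), val), lam) for lam in grid]
    return min(scores)[1]


def _tune_kernel_ridge(X, y, val: WindowedDataset,
                       lam: float | None, gam: float | None) -> tuple[float, float]:
    lam_grid = [lam] if lam is not None else [1e-3, 1e-2, 1e-1, 1.0, 10.0]
    gam_grid = [gam] if gam is not None else [1e-3, 1e-2, 1e-1, 1.0, 10.0]
    if len(val) == 0:
        return (lam if lam is not None else 1.0, gam if gam is not None else 0.1)
    scores = [
        (_val_rmse(kernel_ridge_fit(X, y, la, ga), val), la, ga)
        for la, ga in product(lam_grid, gam_grid)
    ]
    best = min(scores)
    return best[1], best[2]
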