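"""Bayesian optimization of the three LSTM hyperparameters.

The tuned quantities are dropout rate, number of LSTM units, and number of
feed-forward (dense head) units, over the box (0.10, 5, 5)-(0.45, 60, 40)
with unit changes (0.01, 1, 1) — a full grid of 35*55*35 = 67,375 settings.
Instead of exhausting the grid, the optimizer:

1. evaluates a seeded Latin hypercube design (default 15 settings; exactly
   one sample per equal-probability stratum per dimension);
2. fits a Gaussian-process surrogate (anisotropic squared-exponential kernel
   with a small noise floor, outputs standardized) to (setting, validation
   RMSE) pairs;
3. proposes the next setting by maximizing expected improvement (EI) over
   the discretized space with multi-start random + neighborhood search;
4. stops when a proposed evaluation fails to improve the incumbent RMSE
   (patience 1, relative tolerance 1e-3 by default) or the budget runs out.

Integer dimensions are searched by continuous relaxation and rounded to the
nearest valid step at evaluation time; Latin hypercube samples are re-placed
within their stratum when rounding would leave it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from glucoforecast.forecaster import LSTMConfig, train
from glucoforecast.preprocess import PreparedPatient


@dataclass(frozen=True)
class SearchSpace:
    """Box-with-steps search space; defaults are the LSTM tuning bounds."""

    lower: tuple[float, ...] = (0.10, 5.0, 5.0)
    upper: tuple[float, ...] = (0.45, 60.0, 40.0)
    step: tuple[float, ...] = (0.01, 1.0, 1.0)
    names: tuple[str, ...] = ("dropout_rate", "n_lstm_units", "n_dense_units")
    integer: tuple[bool, ...] = (False, True, True)

    def __post_init__(self) -> None:
        d = len(self.lower)
        if not (len(self.upper) == len(self.step) == len(self.integer) == d):
            raise ValueError("dimension mismatch in SearchSpace fields")
        for lo, hi in zip(self.lower, self.upper):
            if hi < lo:
                raise ValueError("upper bound below lower bound")

    @property
    def ndim(self) -> int:
        return len(self.lower)

    def snap(self, x: np.ndarray) -> np.ndarray:
        """Round a point to the nearest valid step values, within bounds."""
        x = np.asarray(x, dtype=float)
        lo = np.array(self.lower)
        st = np.array(self.step)
        snapped = lo + np.round((x - lo) / st) * st
        return np.clip(snapped, self.lower, self.upper)


def grid_size(space: SearchSpace) -> int:
    """Number of grid combinations, counting (upper - lower)/step per
    dimension (no +1); a degenerate dimension contributes 0 with a warning."""
    total = 1
    for name, lo, hi, st in zip(space.names, space.lower, space.upper, space.step):
        span = hi - lo
        count = span / st
        if abs(count - round(count)) > 1e-9:
            raise ValueError(f"range of {name} is not divisible by its step")
        count = int(round(count))
        if count == 0:
            warnings.warn(f"degenerate search dimension {name} (upper == lower)")
        total *= count
    return total


def stratum_index(x: np.ndarray, space: SearchSpace, dim: int, n: int) -> np.ndarray:
    """Which of n equal strata each value falls in, along one dimension."""
    lo, hi = space.lower[dim], space.upper[dim]
    idx = np.floor((np.asarray(x) - lo) / (hi - lo) * n).astype(int)
    return np.clip(idx, 0, n - 1)


def latin_hypercube(space: SearchSpace, n: int, seed: int = 0) -> np.ndarray:
    """Seeded Latin hypercube design: one sample per stratum per dimension.

    Integer dimensions are rounded to the nearest step value *inside* the
    source stratum (re-placed within the stratum if plain rounding would
    cross a boundary), so the one-per-stratum property survives rounding
    whenever each stratum contains at least one valid value.
    """
    if n < 2:
        raise ValueError("Latin hypercube design needs n >= 2")
    rng = np.random.default_rng(seed)
    out = np.empty((n, space.ndim))
    for d in range(space.ndim):
        lo, hi, st = space.lower[d], space.upper[d], space.step[d]
        perm = rng.permutation(n)
        u = rng.random(n)
        x = lo + (perm + u) / n * (hi - lo)
        if space.integer[d] or st > 0:
            snapped = lo + np.round((x - lo) / st) * st
            width = (hi - lo) / n
            for i in range(n):
                s_lo = lo + perm[i] * width
                s_hi = lo + (perm[i] + 1) * width
                inside = snapped[i] >= s_lo and (
                    snapped[i] < s_hi or (perm[i] == n - 1 and snapped[i] <= hi)
                )
                if not inside:
                    # nearest valid step value inside the stratum, if any
                    # (upper edge exclusive except for the last stratum)
                    k_lo = int(np.ceil((s_lo - lo) / st - 1e-12))
                    k_hi = int(np.floor((min(s_hi, hi) - lo) / st + 1e-12))
                    if perm[i] < n - 1 and lo + k_hi * st >= s_hi - 1e-12:
                        k_hi -= 1
                    if k_lo <= k_hi:
                        ks = np.arange(k_lo, k_hi + 1)
                        vals = lo + ks * st
                        snapped[i] = vals[np.argmin(np.abs(vals - x[i]))]
                    # else: stratum thinner than a step; keep nearest overall
            x = np.clip(snapped, lo, hi)
        out[:, d] = x
    return out


class GPPosterior:
    """Gaussian-process surrogate over the (normalized) search space."""

    def __init__(self, gp: GaussianProcessRegressor, x_lo: np.ndarray, x_span: np.ndarray):
        self._gp = gp
        self._x_lo = x_lo
        self._x_span = x_span

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xn = (X - self._x_lo) / self._x_span
        mu, sd = self._gp.predict(Xn, return_std=True)
        return mu, sd


def fit_gp(evaluated: list[tuple[np.ndarray, float]],
           space: SearchSpace | None = None) -> GPPosterior:
    """Fit the GP surrogate to (setting, RMSE) pairs.

    Inputs are mapped to the unit cube; outputs are standardized inside the
    regressor.  Duplicate settings with conflicting RMSE are averaged with a
    warning.  Kernel: constant * anisotropic RBF + white noise floor, scales
    fitted by marginal-likelihood maximization.
    """
    if len(evaluated) < 2:
        raise ValueError("need at least two evaluated settings to fit a GP")
    X = np.array([np.asarray(s, dtype=float) for s, _ in evaluated])
    y = np.array([r for _, r in evaluated], dtype=float)
    # collapse duplicates
    uniq, inv = np.unique(X, axis=0, return_inverse=True)
    if len(uniq) < len(X):
        warnings.warn("duplicate settings with conflicting RMSE: averaging")
        y = np.array([y[inv == i].mean() for i in range(len(uniq))])
        X = uniq
    if len(X) < 2:
        raise ValueError("need at least two distinct settings to fit a GP")
    if space is not None:
        x_lo = np.array(space.lower, dtype=float)
        x_span = np.array(space.upper, dtype=float) - x_lo
    else:
        x_lo = X.min(axis=0)
        x_span = X.max(axis=0) - x_lo
    x_span = np.where(x_span > 0, x_span, 1.0)
    d = X.shape[1]
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2))
        + WhiteKernel(1e-6, (1e-10, 1e-1))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=2, random_state=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit((X - x_lo) / x_span, y)
    return GPPosterior(gp, x_lo, x_span)


def expected_improvement(gp: GPPosterior, setting: np.ndarray,
                         incumbent_rmse: float) -> float | np.ndarray:
    """Closed-form EI for minimization; zero where the posterior SD is zero.

    With z = (incumbent - mu)/sd:  EI = (incumbent - mu)*Phi(z) + sd*phi(z).
    """
    mu, sd = gp.predict(setting)
    ei = np.zeros_like(mu)
    ok = sd > 1e-12
    z = (incumbent_rmse - mu[ok]) / sd[ok]
    ei[ok] = (incumbent_rmse - mu[ok]) * norm.cdf(z) + sd[ok] * norm.pdf(z)
    ei = np.maximum(ei, 0.0)
    return float(ei[0]) if np.ndim(setting) == 1 else ei


@dataclass
class BOState:
    """Audit trail of one optimization run."""

    evaluated: list[tuple[np.ndarray, float]] = field(default_factory=list)
    failed: list[np.ndarray] = field(default_factory=list)
    incumbent: tuple[np.ndarray, float] | None = None
    trail: list[dict] = field(default_factory=list)

    def trail_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trail)

    def record(self, setting: np.ndarray, rmse: float | None, names) -> None:
        row = {"iteration": len(self.trail), **dict(zip(names, setting))}
        if rmse is None:
            row["val_rmse"] = np.nan
            self.failed.append(setting)
        else:
            row["val_rmse"] = rmse
            self.evaluated.append((setting, rmse))
            if self.incumbent is None or rmse < self.incumbent[1]:
                self.incumbent = (setting, rmse)
        row["incumbent_rmse"] = self.incumbent[1] if self.incumbent else np.nan
        self.trail.append(row)


def _propose(gp: GPPosterior, space: SearchSpace, incumbent: tuple[np.ndarray, float],
             seen: set, rng: np.random.Generator, n_candidates: int = 2048) -> np.ndarray:
    """Maximize EI over the discretized space: random multi-start plus a
    neighborhood sweep around the incumbent."""
    lo = np.array(space.lower)
    hi = np.array(space.upper)
    st = np.array(space.step)
    cand = rng.uniform(lo, hi, size=(n_candidates, space.ndim))
    # local candidates: incumbent +- up to 3 steps per dimension
    offsets = rng.integers(-3, 4, size=(128, space.ndim)) * st
    local = incumbent[0] + offsets
    cand = np.vstack([cand, local])
    cand = np.clip(lo + np.round((cand - lo) / st) * st, lo, hi)
    ei = expected_improvement(gp, cand, incumbent[1])
    order = np.argsort(-ei)
    for i in order:
        key = tuple(np.round(cand[i], 10))
        if key not in seen:
            return cand[i]
    return cand[order[0]]  # space exhausted: return best even if seen


def optimize(
    objective,
    space: SearchSpace | None = None,
    seed: int = 0,
    budget: int = 40,
    n_init: int = 15,
    patience: int = 1,
    rel_tol: float = 1e-3,
) -> tuple[np.ndarray, BOState]:
    """Run the full loop: LHD -> (GP -> EI -> evaluate) -> stop.

    ``objective`` maps a setting vector to validation RMSE; an exception
    marks the setting as failed (excluded from the GP) and the run continues.
    Returns the incumbent setting and the audit trail.  Deterministic for a
    fixed seed and objective.
    """
    space = space or SearchSpace()
    if budget < n_init:
        raise ValueError(f"budget ({budget}) must be >= initial design size ({n_init})")
    rng = np.random.default_rng(seed)
    state = BOState()
    seen: set = set()

    design = latin_hypercube(space, n_init, seed=seed)
    for setting in design:
        setting = space.snap(setting)
        seen.add(tuple(np.round(setting, 10)))
        try:
            rmse = float(objective(setting))
        except Exception:
            rmse = None
        state.record(setting, rmse, space.names)

    no_improve = 0
    while len(state.trail) < budget and state.incumbent is not None:
        if len(state.evaluated) < 2:
            setting = space.snap(rng.uniform(space.lower, space.upper))
        else:
            gp = fit_gp(state.evaluated, space)
            setting = _propose(gp, space, state.incumbent, seen, rng)
        seen.add(tuple(np.round(setting, 10)))
        before = state.incumbent[1]
        try:
            rmse = float(objective(setting))
        except Exception:
            rmse = None
        state.record(setting, rmse, space.names)
        improved = rmse is not None and rmse < before * (1.0 - rel_tol)
        no_improve = 0 if improved else no_improve + 1
        if no_improve >= patience:
            break
    if state.incumbent is None:
        raise RuntimeError("every evaluation failed; nothing to return")
    return state.incumbent[0], state


def lstm_objective(prep: PreparedPatient, base_config: LSTMConfig):
    """Objective closure for tuning one patient's LSTM: setting -> val RMSE
    in mg/dL.  Integer dimensions arrive as floats and are rounded here."""

    def objective(setting: np.ndarray) -> float:
        cfg = dc_replace(
            base_config,
            dropout_rate=float(setting[0]),
            n_lstm_units=int(round(setting[1])),
            n_dense_units=int(round(setting[2])),
        )
        result = train(prep.train, prep.val, cfg, scaler=prep.scaler)
        return result.best_val_rmse

    return objective
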