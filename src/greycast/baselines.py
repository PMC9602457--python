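"""Classical comparison forecasters: simple exponential smoothing and
logistic growth.

These are the conventional statistical references a grey model is judged
against on short demographic series.  Both follow the same estimator
shape as the grey families (fit on training values, predict a horizon)
so they drop into the same evaluation and tabulation code.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .series import MIN_LENGTH

__all__ = ["BaselineError", "SimpleExponentialSmoother", "LogisticGrowth"]


class BaselineError(ValueError):
    """A baseline model could not be fitted."""


class SimpleExponentialSmoother(BaseEstimator):
    """Simple exponential smoothing with a grid-selected weight.

    The level starts at the first observation and follows

        level_t = w * x_t + (1 - w) * level_{t-1},

    with the fitted value for year t being the level *before* observing
    x_t (a one-step-ahead forecast; at w = 1 this is the naive forecast).
    When ``weight`` is None it is chosen on the grid 0.01..1.00 (step
    0.01) to minimize the training one-step-ahead MAPE.  Multi-step
    forecasts are flat at the final level.
    """

    def __init__(self, weight: float | None = None):
        self.weight = weight

    @staticmethod
    def _smooth(y: np.ndarray, w: float):
        fitted = np.empty_like(y)
        level = y[0]
        for t, x in enumerate(y):
            fitted[t] = level
            level = w * x + (1.0 - w) * level
        return fitted, level

    def fit(self, y, X=None):
        y = np.asarray(y, dtype=float).ravel()
        if y.size < 2:
            raise BaselineError("exponential smoothing needs at least 2 points")
        if np.any(y <= 0):
            raise BaselineError("series must be positive for percentage errors")
        if self.weight is not None:
            if not 0.0 < self.weight <= 1.0:
                raise BaselineError(f"weight must lie in (0, 1], got {self.weight}")
            grid = [float(self.weight)]
        else:
            grid = [round(0.01 * k, 2) for k in range(1, 101)]
        best = None
        for w in grid:
            fitted, level = self._smooth(y, w)
            score = float(np.mean(np.abs(fitted - y) / y))
            if best is None or score < best[0]:
                best = (score, w, fitted, level)
        _, self.weight_, self.fitted_values_, self.level_ = best
        self.n_train_ = int(y.size)
        return self

    def predict(self, horizon: int = 1) -> np.ndarray:
        if not hasattr(self, "level_"):
            raise BaselineError("not fitted yet")
        return np.full(int(horizon), self.level_)


def _logistic(t, K, r, t0):
    return K / (1.0 + np.exp(-r * (t - t0)))


class LogisticGrowth(BaseEstimator):
    """Saturating logistic curve x(t) = K / (1 + exp(-r (t - t0))).

    Fitted by nonlinear least squares over multiple starts (capacity K
    seeded at 1.05-2x the observed maximum, both growth signs tried).
    Decreasing series are admissible via r < 0.
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def fit(self, y, X=None):
        y = np.asarray(y, dtype=float).ravel()
        if y.size < MIN_LENGTH:
            raise BaselineError(
                f"logistic fit needs at least {MIN_LENGTH} points, got {y.size}"
            )
        t = np.arange(y.size, dtype=float)
        slope = np.polyfit(t, y, 1)[0]
        r0 = np.sign(slope) if slope != 0 else 1.0
        best = None
        for k_scale in (1.05, 1.2, 1.5, 2.0):
            for r_init in (0.1 * r0, 0.5 * r0, 1.0 * r0, -0.1 * r0):
                if r_init == 0:
                    continue
                p0 = (k_scale * y.max(), r_init, 0.5 * y.size)
                try:
                    popt, _ = curve_fit(_logistic, t, y, p0=p0, maxfev=self.maxfev)
                except (RuntimeError, ValueError):
                    continue
                if popt[0] <= 0:
                    continue
                sse = float(np.sum((_logistic(t, *popt) - y) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, popt)
        if best is None:
            raise BaselineError("logistic fit failed to converge from every start")
        self.K_, self.r_, self.t0_ = (float(v) for v in best[1])
        self.fitted_values_ = _logistic(t, self.K_, self.r_, self.t0_)
        self.n_train_ = int(y.size)
        return self

    def predict(self, horizon: int = 1) -> np.ndarray:
        if not hasattr(self, "K_"):
            raise BaselineError("not fitted yet")
        t = np.arange(self.n_train_, self.n_train_ + int(horizon), dtype=float)
        return _logistic(t, self.K_, self.r_, self.t0_)
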