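"""Grey forecasting model families as scikit-learn style estimators.

All four families solve the same grey Bernoulli difference equation on an
accumulated sequence,

    x_zeta(k) - x_zeta(k-1) + a * z(k) = b * z(k)**alpha,   k = 2..n,

where z(k) is the adjacent mean of the zeta-order damping accumulation of
the data, ``a`` is the development coefficient and ``b`` the grey action
quantity.  (a, b) are estimated by linear least squares; forecasts come
from the closed-form time response of the associated whitening ODE,

    xhat_zeta(k+1) = [ b/a + (x1**(1-alpha) - b/a) * exp(-(1-alpha)*a*k) ]**(1/(1-alpha)),

anchored at xhat_zeta(1) = x0(1), then restored to the original scale by
the inverse damping operator.  The family tree:

============  =====  ======
family        alpha  zeta
============  =====  ======
GM11          0      1
NGBM          free   1
DampedGM11    0      free
DampedNGBM    free   free
============  =====  ======

Setting zeta = 1 in a damped family reproduces its classical counterpart
output-for-output; alpha = 0 turns the Bernoulli equation linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .accumulation import damping_accumulate, damping_restore, mean_sequence
from .series import MIN_LENGTH, AnnualSeries

__all__ = [
    "GreyModelError",
    "InvalidExponentError",
    "NonPositiveBackgroundError",
    "RankDeficientError",
    "DegenerateModelError",
    "PositivityError",
    "ForecastResult",
    "build_design",
    "least_squares",
    "GreyForecaster",
    "DampedNGBM",
    "DampedGM11",
    "NGBM",
    "GM11",
    "FAMILIES",
    "make_forecaster",
]

# below this magnitude the development coefficient makes b/a meaningless
_A_TINY = 1e-12


class GreyModelError(ValueError):
    """Base class for grey-model fitting/forecasting errors."""


class InvalidExponentError(GreyModelError):
    """alpha = 1 makes the Bernoulli exponent 1/(1-alpha) singular."""


class NonPositiveBackgroundError(GreyModelError):
    """A background value z(k) <= 0 cannot be raised to a fractional power."""


class RankDeficientError(GreyModelError):
    """The design matrix has collinear columns (e.g. constant accumulation)."""


class DegenerateModelError(GreyModelError):
    """The estimated development coefficient is numerically zero."""


class PositivityError(GreyModelError):
    """The time-response base turned non-positive over the required range."""


@dataclass(frozen=True)
class ForecastResult:
    """Restored model output: in-sample fitted values and out-of-sample predictions."""

    fitted: np.ndarray
    predicted: np.ndarray
    train_years: tuple = ()
    predicted_years: tuple = ()


def build_design(acc, z, alpha: float):
    """Design matrix B and response Y of the grey difference equation.

    B has rows (-z(k), z(k)**alpha); Y(k) = x_zeta(k) - x_zeta(k-1), for
    k = 2..n.  At zeta = 1 the accumulated differences telescope back to
    the original values, recovering the classical GM(1,1)/NGBM system.
    """
    acc = np.asarray(acc, dtype=float)
    z = np.asarray(z, dtype=float)
    alpha = float(alpha)
    if acc.size < 3:
        raise GreyModelError(f"need at least 3 accumulated points, got {acc.size}")
    if z.size != acc.size - 1:
        raise GreyModelError("mean sequence must have one fewer entry than accumulation")
    if not float(alpha).is_integer() and np.any(z <= 0):
        raise NonPositiveBackgroundError(
            "background values must be positive for a fractional power exponent"
        )
    B = np.column_stack([-z, np.power(z, alpha)])
    Y = np.diff(acc)
    return B, Y


def least_squares(B, Y):
    """Minimize ||Y - B (a, b)^T||_2 by a rank-revealing orthogonal solve.

    Numerically equivalent to the normal-equations form (B^T B)^{-1} B^T Y
    but stable when the two columns are nearly collinear.
    """
    B = np.asarray(B, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if B.ndim != 2 or B.shape[1] != 2 or B.shape[0] < 2:
        raise GreyModelError(f"design matrix must be (m>=2, 2), got {B.shape}")
    sol, _, rank, _ = np.linalg.lstsq(B, Y, rcond=None)
    if rank < 2:
        raise RankDeficientError("design matrix is rank deficient")
    a, b = float(sol[0]), float(sol[1])
    return a, b


def _time_response(a, b, x1, alpha, k):
    """Accumulated-scale time response xhat_zeta(k+1) at integer offsets k >= 0."""
    k = np.asarray(k, dtype=float)
    one_minus = 1.0 - alpha
    ratio = b / a
    base = ratio + (x1**one_minus - ratio) * np.exp(-one_minus * a * k)
    if np.any(base <= 0) or not np.all(np.isfinite(base)):
        raise PositivityError(
            "time-response base is non-positive over the requested range"
        )
    return np.power(base, 1.0 / one_minus)


class GreyForecaster(BaseEstimator):
    """Mixin with the shared fit/predict machinery; not meant for direct use.

    Subclasses declare ``family``, the tunable hyperparameters in
    ``_free_params``, and the MAPE denominator convention their family is
    conventionally reported with.
    """

    family: str = ""
    _free_params: tuple = ()
    default_mape_convention: str = "include_first"

    # -- hyperparameter plumbing -------------------------------------------------
    @property
    def _alpha(self) -> float:
        return float(getattr(self, "alpha", 0.0))

    @property
    def _zeta(self) -> float:
        return float(getattr(self, "zeta", 1.0))

    # -- estimator API -----------------------------------------------------------
    def fit(self, y, X=None):
        """Fit the grey model to the training values.

        Parameters
        ----------
        y : array-like of shape (n,) or AnnualSeries
            Strictly positive training observations, n >= 4.
        X : ignored
            Present for scikit-learn API compatibility.
        """
        if isinstance(y, AnnualSeries):
            train_years = y.years
            y = y.to_array()
        else:
            train_years = ()
            y = np.asarray(y, dtype=float).ravel()
        alpha, zeta = self._alpha, self._zeta
        if alpha == 1.0:
            raise InvalidExponentError("power exponent alpha = 1 is singular")
        if y.size < MIN_LENGTH:
            raise GreyModelError(
                f"need at least {MIN_LENGTH} training points, got {y.size}"
            )

        damped = damping_accumulate(y, zeta)
        z = mean_sequence(damped.values)
        B, Y = build_design(damped.values, z, alpha)
        a, b = least_squares(B, Y)
        if abs(a) < _A_TINY:
            raise DegenerateModelError(
                f"development coefficient |a| = {abs(a):.2e} is numerically zero"
            )

        self.a_ = a
        self.b_ = b
        self.x1_ = float(y[0])
        self.n_train_ = int(y.size)
        self.train_years_ = tuple(train_years)
        # validates positivity of the response over the training range
        self.fitted_values_ = self._restored(self.n_train_)[: self.n_train_]
        return self

    def time_response(self, k):
        """Accumulated-scale response xhat_zeta(k+1) at offset(s) k >= 0."""
        self._check_fitted()
        return _time_response(self.a_, self.b_, self.x1_, self._alpha, k)

    def _restored(self, upto: int) -> np.ndarray:
        """Restored (original-scale) values for indices 1..upto (1-based)."""
        acc = self.time_response(np.arange(upto))
        out = damping_restore(acc, self._zeta)
        out[0] = self.x1_  # exact anchor, immune to b/a cancellation
        return out

    def predict(self, horizon: int = 1) -> np.ndarray:
        """Out-of-sample forecasts for the ``horizon`` years after training."""
        self._check_fitted()
        horizon = int(horizon)
        if horizon < 0:
            raise GreyModelError("horizon must be >= 0")
        if horizon == 0:
            return np.empty(0)
        return self._restored(self.n_train_ + horizon)[self.n_train_ :]

    def forecast(self, horizon: int = 0) -> ForecastResult:
        """Fitted training values plus an out-of-sample forecast."""
        self._check_fitted()
        predicted = self.predict(horizon)
        years = self.train_years_
        pred_years = (
            tuple(years[-1] + i for i in range(1, horizon + 1)) if years else ()
        )
        return ForecastResult(
            fitted=self.fitted_values_.copy(),
            predicted=predicted,
            train_years=years,
            predicted_years=pred_years,
        )

    def _check_fitted(self):
        if not hasattr(self, "a_"):
            raise GreyModelError(
                f"{type(self).__name__} instance is not fitted yet; call fit() first"
            )


class DampedNGBM(GreyForecaster):
    """Nonlinear grey Bernoulli model on a damping-accumulated sequence.

    Parameters
    ----------
    alpha : float, default 0.0
        Bernoulli power exponent (alpha != 1).  0 removes the nonlinearity,
        2 gives a grey Verhulst-type model.
    zeta : float, default 1.0
        Damping coefficient in (0, 1]; smaller values weight recent
        observations more heavily.  zeta = 1 degenerates to the NGBM.
    """

    family = "da_ngbm"
    _free_params = ("alpha", "zeta")
    default_mape_convention = "include_first"

    def __init__(self, alpha: float = 0.0, zeta: float = 1.0):
        self.alpha = alpha
        self.zeta = zeta


class DampedGM11(GreyForecaster):
    """GM(1,1) on a damping-accumulated sequence (alpha fixed at 0)."""

    family = "da_gm11"
    _free_params = ("zeta",)
    default_mape_convention = "include_first"

    def __init__(self, zeta: float = 1.0):
        self.zeta = zeta


class NGBM(GreyForecaster):
    """Classical nonlinear grey Bernoulli model (1-AGO, free power exponent)."""

    family = "ngbm"
    _free_params = ("alpha",)
    default_mape_convention = "exclude_first"

    def __init__(self, alpha: float = 0.0):
        self.alpha = alpha


class GM11(GreyForecaster):
    """Classical GM(1,1): linear grey model on the 1-AGO sequence, no hyperparameters."""

    family = "gm11"
    _free_params = ()
    default_mape_convention = "exclude_first"

    def __init__(self):
        pass


FAMILIES = {cls.family: cls for cls in (GM11, NGBM, DampedGM11, DampedNGBM)}


def make_forecaster(family: str, alpha: float | None = None, zeta: float | None = None):
    """Instantiate a family by name, passing only the hyperparameters it owns."""
    try:
        cls = FAMILIES[family.lower()]
    except KeyError:
        raise GreyModelError(
            f"unknown family {family!r}; choose from {sorted(FAMILIES)}"
        ) from None
    kwargs = {}
    if alpha is not None:
        if "alpha" not in cls._free_params:
            raise GreyModelError(f"{family} has no free power exponent")
        kwargs["alpha"] = alpha
    if zeta is not None:
        if "zeta" not in cls._free_params:
            raise GreyModelError(f"{family} has no free damping coefficient")
        kwargs["zeta"] = zeta
    return cls(**kwargs)
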