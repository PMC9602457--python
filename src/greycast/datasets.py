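"""Bundled case-study series and a synthetic grey-series generator.

The three bundled fixtures are short demographic sequences (2011-2020):
China's national birth rate (per-mille scale), the registered population
of Jiangsu province and the male population of Nanjing city (both in tens
of thousands of people).  Values are stored to the two decimals of the
published statistical yearbooks.

:func:`generate_synthetic` manufactures series that lie exactly in the
solution set of a chosen grey family, optionally perturbed with additive
Gaussian noise, for round-trip and recovery testing.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .accumulation import damping_restore
from .models import InvalidExponentError
from .series import AnnualSeries, SeriesValidationError

__all__ = ["FIXTURE_NAMES", "builtin_fixture", "list_fixtures", "generate_synthetic"]

_YEARS = tuple(range(2011, 2021))

_FIXTURES = {
    "china_birth_rate": AnnualSeries(
        _YEARS,
        (13.27, 14.57, 13.03, 13.83, 11.99, 13.57, 12.64, 10.86, 10.41, 8.52),
        name="china_birth_rate",
        unit="%",
    ),
    "jiangsu_registered": AnnualSeries(
        _YEARS,
        (7514.25, 7553.48, 7616.84, 7684.69, 7717.59,
         7775.66, 7794.19, 7831.86, 7858.27, 7876.75),
        name="jiangsu_registered",
        unit="ten thousand people",
    ),
    "nanjing_male": AnnualSeries(
        _YEARS,
        (320.90, 321.39, 322.90, 325.04, 326.78,
         330.86, 339.27, 346.85, 352.80, 358.64),
        name="nanjing_male",
        unit="ten thousand people",
    ),
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def builtin_fixture(name: str) -> AnnualSeries:
    """Return one of the bundled annual series by name."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None


def list_fixtures() -> tuple:
    return FIXTURE_NAMES


def _next_accumulated(u: float, a: float, b: float, alpha: float) -> float:
    """Solve x_zeta(k) - u + a*z = b*z**alpha for x_zeta(k), z = (u + x)/2."""
    if alpha == 0.0:
        denom = 1.0 + a / 2.0
        if denom == 0.0:
            raise SeriesValidationError("parameter set degenerate: 1 + a/2 = 0")
        return (u * (1.0 - a / 2.0) + b) / denom

    def g(v):
        z = 0.5 * (u + v)
        return v - u + a * z - b * np.power(z, alpha)

    # bracket a root with v > u so the restored increment stays positive
    lo = u * (1.0 + 1e-12)
    hi = max(2.0 * u, u + 1.0)
    for _ in range(200):
        if g(lo) * g(hi) < 0:
            return brentq(g, lo, hi, xtol=1e-14, rtol=1e-15)
        hi *= 2.0
        if not np.isfinite(hi):
            break
    raise SeriesValidationError(
        "parameter set does not generate a positive, increasing accumulated sequence"
    )


def generate_synthetic(
    a: float,
    b: float,
    alpha: float,
    zeta: float,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    x1: float | None = None,
    start_year: int = 2011,
    name: str = "synthetic",
) -> AnnualSeries:
    """Generate a series the chosen grey family fits with zero residual.

    The accumulated sequence is propagated through the family's grey
    difference equation step by step (closed form at alpha = 0, a scalar
    root-find otherwise), then restored to the original scale.  With
    ``noise_sd = 0`` least squares on the result recovers (a, b) to
    machine precision.  Noise, when requested, is additive Gaussian on the
    restored values.

    Parameters
    ----------
    a, b : float
        Development coefficient and grey action quantity.
    alpha : float
        Power exponent (alpha != 1).
    zeta : float
        Damping coefficient in (0, 1].
    n : int
        Series length, >= 4.
    noise_sd : float
        Standard deviation of additive Gaussian noise (0 = exact series).
    seed : int
        Seed for the noise generator; ignored when noise_sd = 0.
    x1 : float, optional
        First observation; defaults to ``abs(b)`` (or 1.0 if b = 0).
    """
    if alpha == 1.0:
        raise InvalidExponentError("power exponent alpha = 1 is singular")
    if not 0.0 < zeta <= 1.0:
        raise SeriesValidationError(f"zeta must lie in (0, 1], got {zeta}")
    if n < 4:
        raise SeriesValidationError(f"need n >= 4, got {n}")
    if noise_sd < 0:
        raise SeriesValidationError("noise_sd must be >= 0")
    if x1 is None:
        x1 = abs(b) if b != 0 else 1.0
    if x1 <= 0:
        raise SeriesValidationError("first value must be positive")

    acc = np.empty(n)
    acc[0] = x1
    for k in range(1, n):
        acc[k] = _next_accumulated(acc[k - 1], a, b, alpha)
    values = damping_restore(acc, zeta)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=n)
    if np.any(values <= 0):
        raise SeriesValidationError(
            "parameter set (or noise draw) produced non-positive values"
        )
    return AnnualSeries(
        tuple(range(start_year, start_year + n)),
        tuple(values),
        name=name,
        unit="synthetic units",
    )
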