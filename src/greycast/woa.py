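"""Whale optimization algorithm (WOA) and grey-model hyperparameter tuning.

WOA is a population metaheuristic for bounded continuous minimization
modelled on humpback bubble-net hunting.  Each iteration, every whale
either (p >= 0.5) spirals toward the incumbent best position,

    x <- |x* - x| * exp(b*l) * cos(2*pi*l) + x*,   l ~ U[-1, 1],

or encircles it / searches at random depending on the magnitude of the
coefficient A = 2*a*r1 - a, where the convergence factor a decays
linearly from 2 to 0 over the run: |A| < 1 contracts toward the best
(exploitation), |A| >= 1 moves relative to a randomly chosen whale
(exploration).  Positions are clamped to the search box and the global
best is never lost (elitist trace).

:func:`tune` wraps this around the grey families: the fitness of a
candidate hyperparameter vector is the training-set fitting MAPE of the
model it parameterizes, with infeasible fits (positivity or rank
failures) scored as +inf.  Only the training slice enters the fitness, so
held-out years stay untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import mape
from .models import FAMILIES, GreyModelError
from .series import AnnualSeries, TrainTestSplit

__all__ = [
    "WOAError",
    "NothingToTuneError",
    "WOAConfig",
    "WOAResult",
    "TuneResult",
    "convergence_factor",
    "woa_minimize",
    "tune",
    "DEFAULT_BOUNDS",
]

# search boxes covering the hyperparameter ranges grey practice uses
DEFAULT_BOUNDS = {"alpha": (-1.0, 1.0), "zeta": (0.01, 1.0)}


class WOAError(ValueError):
    """Invalid optimizer configuration or an infeasible problem."""


class NothingToTuneError(WOAError):
    """The requested family has no free hyperparameters."""


@dataclass(frozen=True)
class WOAConfig:
    """Optimizer settings.

    ``bounds`` is one (lower, upper) pair per search dimension.  The
    population and iteration defaults (30 whales, 50 iterations) are the
    conventional WOA choices for low-dimensional problems.
    """

    bounds: tuple
    pop_size: int = 30
    max_iter: int = 50
    spiral_b: float = 1.0
    seed: int = 0

    def __post_init__(self):
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", bounds)
        if not bounds:
            raise WOAError("need at least one search dimension")
        for lo, hi in bounds:
            if not lo < hi:
                raise WOAError(f"lower bound must be < upper bound, got ({lo}, {hi})")
        if self.pop_size < 2:
            raise WOAError(f"pop_size must be >= 2, got {self.pop_size}")
        if self.max_iter < 1:
            raise WOAError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass(frozen=True)
class WOAResult:
    """Best position/fitness found and the per-iteration elitist trace."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray


def convergence_factor(t: int, t_max: int) -> float:
    """Linearly decaying exploration factor: 2 at t = 0, 0 at t = t_max."""
    return 2.0 - 2.0 * t / t_max


def woa_minimize(objective, config: WOAConfig) -> WOAResult:
    """Minimize ``objective`` over the box in ``config`` with WOA.

    ``objective`` maps a position vector to a float and may return +inf for
    infeasible points.  Fully deterministic for a fixed config (including
    seed).
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    dim = lo.size
    n = config.pop_size

    positions = rng.uniform(lo, hi, size=(n, dim))
    fitness = np.array([float(objective(p)) for p in positions])
    if not np.any(np.isfinite(fitness)):
        raise WOAError("every whale in the initial population has infinite fitness")

    best_idx = int(np.argmin(fitness))  # first minimum wins ties
    best_pos = positions[best_idx].copy()
    best_fit = float(fitness[best_idx])
    trace = np.empty(config.max_iter)

    for t in range(config.max_iter):
        a = convergence_factor(t, config.max_iter)
        for i in range(n):
            p = rng.random()
            A = 2.0 * a * rng.random() - a
            C = 2.0 * rng.random()
            if p >= 0.5:  # logarithmic-spiral (bubble-net) update
                l = rng.uniform(-1.0, 1.0)
                dist = np.abs(best_pos - positions[i])
                new = dist * np.exp(config.spiral_b * l) * np.cos(2.0 * np.pi * l) + best_pos
            elif abs(A) < 1.0:  # encircle the incumbent best
                dist = np.abs(C * best_pos - positions[i])
                new = best_pos - A * dist
            else:  # random exploration against another whale
                other = positions[int(rng.integers(n))]
                dist = np.abs(C * other - positions[i])
                new = other - A * dist
            new = np.clip(new, lo, hi)
            positions[i] = new
            fitness[i] = float(objective(new))
        idx = int(np.argmin(fitness))
        if fitness[idx] < best_fit:  # strict: earlier incumbent wins ties
            best_fit = float(fitness[idx])
            best_pos = positions[idx].copy()
        trace[t] = best_fit

    return WOAResult(best_position=best_pos, best_fitness=best_fit, trace=trace)


@dataclass(frozen=True)
class TuneResult:
    """Tuned hyperparameters, the fitted model they produce, and the WOA run."""

    params: dict
    model: object
    woa: WOAResult


def tune(
    series: AnnualSeries,
    family,
    split: TrainTestSplit | None = None,
    config: WOAConfig | None = None,
    *,
    pop_size: int = 30,
    max_iter: int = 50,
    seed: int = 0,
    bounds: dict | None = None,
    convention: str | None = None,
) -> TuneResult:
    """Select a family's free hyperparameters by minimizing training MAPE.

    Parameters
    ----------
    family : forecaster class or family name
        DampedNGBM tunes (alpha, zeta); NGBM tunes alpha; DampedGM11 tunes
        zeta; GM11 raises (nothing to tune).
    config : WOAConfig, optional
        Full optimizer settings; overrides the keyword shortcuts.
    bounds : dict, optional
        Per-hyperparameter (lower, upper) overrides of
        :data:`DEFAULT_BOUNDS`.
    convention : str, optional
        MAPE denominator convention for the fitness; defaults to the
        family's reporting convention.
    """
    if isinstance(family, str):
        try:
            family = FAMILIES[family.lower()]
        except KeyError:
            raise GreyModelError(f"unknown family {family!r}") from None
    free = family._free_params
    if not free:
        raise NothingToTuneError(f"{family.__name__} has no free hyperparameters")

    if split is None:
        split = TrainTestSplit()
    split.validate_for(len(series))
    train = series.train_values(split)
    if convention is None:
        convention = family.default_mape_convention

    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    if config is None:
        config = WOAConfig(
            bounds=tuple(box[name] for name in free),
            pop_size=pop_size,
            max_iter=max_iter,
            seed=seed,
        )
    elif len(config.bounds) != len(free):
        raise WOAError(
            f"{family.__name__} tunes {len(free)} parameter(s) but config has "
            f"{len(config.bounds)} bound(s)"
        )

    def objective(vec):
        params = dict(zip(free, vec))
        model = family(**params)
        try:
            model.fit(train)
            return mape(train, model.fitted_values_, convention)
        except GreyModelError:
            return np.inf

    result = woa_minimize(objective, config)
    params = dict(zip(free, (float(v) for v in result.best_position)))
    model = family(**params).fit(train)
    return TuneResult(params=params, model=model, woa=result)
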