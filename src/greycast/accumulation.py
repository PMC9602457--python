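"""Accumulation-generation operators.

Grey models never fit the raw sequence directly: they first smooth it with
a cumulative operator.  This module provides the classical r-order
accumulated generating operation (r-AGO), the damping accumulated operator

    x_zeta(k) = sum_{i=1..k} x0(i) / zeta**(i-1),   0 < zeta <= 1,

its exact inverse (restoration), adjacent-mean ("background value")
sequences, and the information difference between consecutive accumulated
terms.  At zeta = 1 the damping operator coincides with 1-AGO, so every
classical construction is the degenerate case of the damped one.

Sequences follow the field's 1-based convention k = 1..n in documentation;
arrays are ordinary 0-based NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AccumulationError",
    "DampedSeries",
    "ago",
    "damping_accumulate",
    "damping_restore",
    "mean_sequence",
    "information_difference",
]


class AccumulationError(ValueError):
    """Invalid input to an accumulation operator."""


def _check_zeta(zeta: float) -> float:
    zeta = float(zeta)
    if not 0.0 < zeta <= 1.0:
        raise AccumulationError(f"damping coefficient must lie in (0, 1], got {zeta}")
    return zeta


def _damping_weights(n: int, zeta: float) -> np.ndarray:
    # 1/zeta**(i-1) via running product: stable for small zeta, short n
    w = np.empty(n)
    w[0] = 1.0
    for i in range(1, n):
        w[i] = w[i - 1] / zeta
    return w


@dataclass(frozen=True)
class DampedSeries:
    """A zeta-order damping accumulation together with its zeta.

    ``origin_first`` caches x0(1), which anchors both the model's initial
    condition and the first restored value.
    """

    values: np.ndarray
    zeta: float
    origin_first: float = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "zeta", _check_zeta(self.zeta))
        first = self.origin_first if self.origin_first is not None else values[0]
        object.__setattr__(self, "origin_first", float(first))

    def __len__(self) -> int:
        return len(self.values)


def ago(x, r: int = 1) -> np.ndarray:
    """r-order accumulated generating operation (running sums applied r times)."""
    if r < 1:
        raise AccumulationError(f"accumulation order must be >= 1, got {r}")
    out = np.asarray(x, dtype=float)
    if out.size == 0:
        raise AccumulationError("cannot accumulate an empty sequence")
    for _ in range(int(r)):
        out = np.cumsum(out)
    return out


def damping_accumulate(x, zeta: float) -> DampedSeries:
    """zeta-order damping accumulation of a positive sequence.

    Recent observations are divided by a smaller power of zeta and hence
    carry more weight — the grey "new information priority" principle.
    """
    zeta = _check_zeta(zeta)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise AccumulationError("cannot accumulate an empty sequence")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise AccumulationError("damping accumulation requires strictly positive input")
    acc = np.cumsum(x * _damping_weights(x.size, zeta))
    return DampedSeries(acc, zeta, origin_first=x[0])


def damping_restore(xd, zeta: float | None = None) -> np.ndarray:
    """Exact inverse of :func:`damping_accumulate`.

    Accepts either a :class:`DampedSeries` or a plain accumulated array plus
    ``zeta``.  The first restored value equals the first accumulated value;
    the k-th (k >= 2, 1-based) is the first difference scaled by zeta**(k-1).
    """
    if isinstance(xd, DampedSeries):
        values, zeta = xd.values, xd.zeta
    else:
        if zeta is None:
            raise AccumulationError("zeta required when restoring a plain array")
        values, zeta = np.asarray(xd, dtype=float), _check_zeta(zeta)
    n = values.size
    out = np.empty(n)
    out[0] = values[0]
    if n > 1:
        powers = np.cumprod(np.full(n - 1, zeta))  # zeta**1 .. zeta**(n-1)
        out[1:] = np.diff(values) * powers
    return out


def mean_sequence(acc) -> np.ndarray:
    """Adjacent means z(k) = (x(k) + x(k-1)) / 2 for k = 2..n (length n-1)."""
    acc = np.asarray(acc, dtype=float)
    if acc.size < 2:
        raise AccumulationError("mean sequence needs at least two accumulated values")
    return 0.5 * (acc[1:] + acc[:-1])


def information_difference(xd: DampedSeries) -> np.ndarray:
    """Differences Delta(k) = x_zeta(k+1) - x_zeta(k), k = 1..n-1.

    Equals x0(k+1)/zeta**k in closed form: the information content each new
    observation adds grows as zeta shrinks.
    """
    if len(xd) < 2:
        raise AccumulationError("information difference needs at least two values")
    return np.diff(xd.values)
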