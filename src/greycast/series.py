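"""Annual time-series container and CSV interchange.

Grey forecasting operates on short, strictly positive annual sequences
(the "original behaviour sequence" X(0)).  :class:`AnnualSeries` enforces
the assumptions every model downstream relies on: consecutive calendar
years, positive values, and at least four observations.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

MIN_LENGTH = 4

__all__ = [
    "AnnualSeries",
    "TrainTestSplit",
    "SeriesError",
    "SeriesValidationError",
    "MalformedRowError",
    "NonNumericValueError",
    "DuplicateYearError",
    "read_series",
    "write_series",
    "MIN_LENGTH",
]


class SeriesError(ValueError):
    """Base class for annual-series errors."""


class SeriesValidationError(SeriesError):
    """The data violate an AnnualSeries invariant (length, positivity, year gaps)."""


class MalformedRowError(SeriesError):
    """A CSV row does not have exactly two fields."""


class NonNumericValueError(SeriesError):
    """A CSV field could not be parsed as a number."""


class DuplicateYearError(SeriesError):
    """The same calendar year appears twice."""


@dataclass(frozen=True)
class AnnualSeries:
    """An ordered sequence of strictly positive annual observations.

    Parameters
    ----------
    years : tuple of int
        Consecutive calendar years (strictly increasing by one).
    values : tuple of float
        Strictly positive observations, one per year.
    name : str
        Free-text label.
    unit : str
        Free-text unit carried as metadata only (e.g. ``"%"`` or
        ``"ten thousand people"``); no unit arithmetic is performed.
    """

    years: tuple = field(default=())
    values: tuple = field(default=())
    name: str = ""
    unit: str = ""

    def __post_init__(self):
        years = tuple(int(y) for y in self.years)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values):
            raise SeriesValidationError(
                f"{len(years)} years but {len(values)} values"
            )
        if len(values) < MIN_LENGTH:
            raise SeriesValidationError(
                f"need at least {MIN_LENGTH} observations for a grey fit, got {len(values)}"
            )
        if len(set(years)) != len(years):
            raise DuplicateYearError(f"duplicate year in {years}")
        for prev, cur in zip(years, years[1:]):
            if cur != prev + 1:
                raise SeriesValidationError(
                    f"years must be consecutive; gap between {prev} and {cur}"
                )
        for y, v in zip(years, values):
            if not math.isfinite(v) or v <= 0:
                raise SeriesValidationError(
                    f"value at {y} must be finite and > 0, got {v}"
                )

    def __len__(self) -> int:
        return len(self.values)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def value_at(self, year: int) -> float:
        try:
            return self.values[self.years.index(year)]
        except ValueError:
            raise KeyError(f"{self.name or 'series'} has no year {year}") from None

    def train_values(self, split: "TrainTestSplit") -> np.ndarray:
        split.validate_for(len(self))
        return self.to_array()[: split.train_length]

    def test_values(self, split: "TrainTestSplit") -> np.ndarray:
        split.validate_for(len(self))
        start = split.train_length
        return self.to_array()[start : start + split.test_length]


@dataclass(frozen=True)
class TrainTestSplit:
    """Chronological split: the first ``train_length`` points fit the model,
    the next ``test_length`` points are held out for prediction error."""

    train_length: int = 8
    test_length: int = 2

    def __post_init__(self):
        if self.train_length < MIN_LENGTH:
            raise SeriesValidationError(
                f"train_length must be >= {MIN_LENGTH}, got {self.train_length}"
            )
        if self.test_length < 0:
            raise SeriesValidationError("test_length must be >= 0")

    def validate_for(self, n: int) -> None:
        if self.train_length + self.test_length > n:
            raise SeriesValidationError(
                f"split {self.train_length}+{self.test_length} exceeds series length {n}"
            )

    def train_years(self, series: AnnualSeries):
        return series.years[: self.train_length]

    def test_years(self, series: AnnualSeries):
        return series.years[self.train_length : self.train_length + self.test_length]


def read_series(path, *, name: str = "", unit: str = "") -> AnnualSeries:
    """Read a two-column ``year,value`` CSV (header required) into an AnnualSeries.

    Raises
    ------
    FileNotFoundError, MalformedRowError, NonNumericValueError,
    DuplicateYearError, SeriesValidationError
    """
    years, values = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedRowError(f"{path}: empty file") from None
        if len(header) != 2:
            raise MalformedRowError(f"{path}: expected 2 header columns, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise MalformedRowError(f"{path}:{lineno}: expected 2 fields, got {row}")
            try:
                year = int(row[0])
            except ValueError:
                raise NonNumericValueError(
                    f"{path}:{lineno}: year {row[0]!r} is not an integer"
                ) from None
            try:
                value = float(row[1])
            except ValueError:
                raise NonNumericValueError(
                    f"{path}:{lineno}: value {row[1]!r} is not numeric"
                ) from None
            if year in years:
                raise DuplicateYearError(f"{path}:{lineno}: duplicate year {year}")
            years.append(year)
            values.append(value)
    return AnnualSeries(tuple(years), tuple(values), name=name or str(path), unit=unit)


def write_series(series: AnnualSeries, path) -> None:
    """Write an AnnualSeries as a ``year,value`` CSV, faithful to repr precision."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "value"])
        for year, value in zip(series.years, series.values):
            writer.writerow([year, repr(value)])
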