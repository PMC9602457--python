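"""Error metrics and the train/test evaluation protocol.

All model comparisons use the mean absolute percentage error

    MAPE = (1/m) * sum_i |xhat(i) - x(i)| / x(i) * 100,

computed separately over the training years ("simulation"/fitting MAPE)
and the held-out years (prediction MAPE).  Two denominator conventions
are supported because published grey-model tables differ in whether the
anchored first year — whose fitted value equals the observation by
construction, error exactly zero — is averaged in:

- ``include_first``: average over all n training years (the damped
  families are conventionally reported this way);
- ``exclude_first``: average over years 2..n (the classical GM(1,1) and
  NGBM convention).

Each forecaster class carries its family's default in
``default_mape_convention``; every function here accepts an override.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .models import GreyModelError
from .series import AnnualSeries, TrainTestSplit

__all__ = [
    "CONVENTIONS",
    "EvaluationReport",
    "ape",
    "mape",
    "evaluate",
    "comparison_table",
    "table_to_text",
]

CONVENTIONS = ("include_first", "exclude_first")


def ape(actual: float, predicted: float) -> float:
    """Absolute percentage error, in percent of the actual value."""
    actual = float(actual)
    if actual <= 0:
        raise ValueError(f"APE needs a positive actual value, got {actual}")
    return 100.0 * abs(float(predicted) - actual) / actual


def mape(actuals, predictions, convention: str = "include_first") -> float:
    """Mean APE under the chosen denominator convention."""
    actuals = np.asarray(actuals, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if actuals.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {actuals.shape} actuals vs {predictions.shape} predictions"
        )
    if actuals.size < 1:
        raise ValueError("MAPE needs at least one point")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")
    if np.any(actuals <= 0):
        raise ValueError("APE needs positive actual values")
    errors = 100.0 * np.abs(predictions - actuals) / actuals
    if convention == "exclude_first":
        if actuals.size < 2:
            raise ValueError("exclude_first needs at least two points")
        errors = errors[1:]
    return float(errors.mean())


@dataclass(frozen=True)
class EvaluationReport:
    """Per-year errors and summary MAPEs for one fitted model on one series."""

    model_name: str
    fitting_ape: dict  # year -> APE (%) over training years
    prediction_ape: dict  # year -> APE (%) over test years
    per_year_fitted: dict  # year -> fitted value
    per_year_predictions: dict  # year -> predicted value
    fitting_mape: float
    prediction_mape: float | None
    convention: str

    def summary(self) -> str:
        lines = [f"model: {self.model_name} (fitting convention: {self.convention})"]
        lines.append(f"fitting MAPE: {self.fitting_mape:.2f}%")
        if self.prediction_mape is not None:
            lines.append(f"prediction MAPE: {self.prediction_mape:.2f}%")
        for year, err in self.prediction_ape.items():
            lines.append(
                f"  {year}: predicted {self.per_year_predictions[year]:.2f}, APE {err:.2f}%"
            )
        return "\n".join(lines)


def evaluate(
    series: AnnualSeries,
    model,
    split: TrainTestSplit,
    horizon: int | None = None,
    convention: str | None = None,
) -> EvaluationReport:
    """Score an already-fitted forecaster against a series under a split.

    Fits nothing: ``model`` must already be fitted on the training slice of
    ``series``.  ``horizon`` defaults to the split's test length and may not
    exceed it (there would be no actuals to score against).
    """
    split.validate_for(len(series))
    if horizon is None:
        horizon = split.test_length
    if horizon > split.test_length:
        raise ValueError(
            f"horizon {horizon} exceeds the {split.test_length} available test years"
        )
    if convention is None:
        convention = getattr(model, "default_mape_convention", "include_first")

    train = series.train_values(split)
    fitted = np.asarray(model.fitted_values_, dtype=float)
    if fitted.size != train.size:
        raise GreyModelError(
            f"model was fitted on {fitted.size} points but the split trains on {train.size}"
        )
    predicted = model.predict(horizon) if horizon > 0 else np.empty(0)
    test = series.test_values(split)[:horizon]

    train_years = split.train_years(series)
    test_years = split.test_years(series)[:horizon]
    fit_ape = {y: ape(a, p) for y, a, p in zip(train_years, train, fitted)}
    pred_ape = {y: ape(a, p) for y, a, p in zip(test_years, test, predicted)}

    return EvaluationReport(
        model_name=type(model).__name__,
        fitting_ape=fit_ape,
        prediction_ape=pred_ape,
        per_year_fitted=dict(zip(train_years, fitted)),
        per_year_predictions=dict(zip(test_years, predicted)),
        fitting_mape=mape(train, fitted, convention),
        prediction_mape=(
            float(np.mean(list(pred_ape.values()))) if pred_ape else None
        ),
        convention=convention,
    )


def comparison_table(
    series: AnnualSeries,
    models,
    split: TrainTestSplit,
    horizon: int | None = None,
) -> pd.DataFrame:
    """Fit several model specs on one series and tabulate values and errors.

    Parameters
    ----------
    models : dict of {label: unfitted estimator}
        Each estimator is cloned, fitted on the training slice, and scored.

    Returns
    -------
    DataFrame indexed by year (plus two MAPE summary rows) with a
    two-level column per model: fitted/predicted value and APE (%).
    Full precision is retained; round only for display.
    """
    if not models:
        raise ValueError("need at least one model spec")
    split.validate_for(len(series))
    if horizon is None:
        horizon = split.test_length

    train_years = list(split.train_years(series))
    test_years = list(split.test_years(series)[:horizon])
    index = train_years + ["fitting MAPE (%)"] + test_years + ["prediction MAPE (%)"]
    actual_col = (
        [series.value_at(y) for y in train_years]
        + [np.nan]
        + [series.value_at(y) for y in test_years]
        + [np.nan]
    )
    data = {("actual", series.unit or "value"): actual_col}

    for label, spec in models.items():
        model = clone(spec)
        model.fit(series.train_values(split))
        report = evaluate(series, model, split, horizon=horizon)
        values = (
            [report.per_year_fitted[y] for y in train_years]
            + [np.nan]
            + [report.per_year_predictions[y] for y in test_years]
            + [np.nan]
        )
        errors = (
            [report.fitting_ape[y] for y in train_years]
            + [report.fitting_mape]
            + [report.prediction_ape[y] for y in test_years]
            + [report.prediction_mape if report.prediction_mape is not None else np.nan]
        )
        data[(label, "value")] = values
        data[(label, "APE (%)")] = errors

    table = pd.DataFrame(data, index=index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["model", "field"])
    return table


def table_to_text(table: pd.DataFrame) -> str:
    """Render a comparison table as aligned plain text, rounded to 2 decimals."""
    return table.round(2).to_string(na_rep="")
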