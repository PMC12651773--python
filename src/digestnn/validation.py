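"""External validation of the simplified model against published data.

Nine literature rows (lentil, quinoa, pearl millet, kiwifruit, sunflower-meal
proteins) report solubility, α-helix and random-coil content together with a
measured in-vitro digestibility and the simplified model's published
prediction.  This module recomputes the error metrics of that comparison —
MAE, RMSE, per-row percentage error — and reports R² in *both* common senses:

* the squared Pearson correlation between measured and predicted values
  (0.91 on the published rows), and
* the coefficient of determination ``1 - SS_res / SS_tot`` (0.90 on the same
  rows).

The two differ whenever predictions are not the least-squares fit of the
measurements, and the published headline value is only reproducible as the
squared correlation, so both are printed with explicit labels.

A freshly trained simplified regressor can also be run on the literature
rows; its inputs may fall outside the training feature ranges, in which case
the report flags extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, DomainError
from .fnn import TrainedRegressor, evaluate
from .synthetic import LiteratureRow, table3_fixture


def percentage_error(measured: float, predicted: float) -> float:
    """Relative error in percent: |predicted - measured| / measured * 100.

    Rounded to 2 decimals for display parity with the published table.
    """
    if measured <= 0:
        raise DomainError("measured digestibility must be positive")
    return round(abs(predicted - measured) / measured * 100.0, 2)


@dataclass(frozen=True)
class ValidationReport:
    """External-comparison rows plus summary metrics (percent scale)."""

    rows: tuple[tuple[str, float, float, float], ...]  # (source, measured, predicted, pct error)
    mae: float
    rmse: float
    r2_pearson_squared: float
    r2_determination: float
    extrapolated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.mae <= self.rmse + 1e-12

    def to_dict(self) -> dict:
        return {
            "rows": [
                {"source": s, "measured": m, "predicted": p, "percentage_error": e}
                for s, m, p, e in self.rows
            ],
            "mae": self.mae,
            "rmse": self.rmse,
            "r2_pearson_squared": self.r2_pearson_squared,
            "r2_determination": self.r2_determination,
            "extrapolated": list(self.extrapolated),
        }


def external_validate(rows: list[LiteratureRow] | None = None,
                      model: TrainedRegressor | None = None,
                      predictions: np.ndarray | None = None) -> ValidationReport:
    """Compare measured literature digestibility with model predictions.

    Without ``model`` or ``predictions`` the fixture's published prediction
    column is validated (self-check mode, exactly reproducing the published
    metrics).  With a trained simplified model, predictions are generated from
    each row's (solubility, α-helix, random-coil) triple through the model's
    own scaler; inputs outside the model's training range are flagged.
    """
    rows = table3_fixture() if rows is None else list(rows)
    if len(rows) < 2:
        raise DataError("external validation needs at least 2 rows")
    measured = np.array([r.digestibility for r in rows])
    extrapolated: list[str] = []
    if predictions is not None:
        pred = np.asarray(predictions, float).ravel()
        if pred.size != len(rows):
            raise DataError("one prediction per row required")
    elif model is not None:
        X = np.array([[r.solubility, r.alpha_helix, r.random_coil] for r in rows])
        fs = model.scaler.subset(model.spec.feature_names)
        for j, name in enumerate(model.spec.feature_names):
            span = 3.0  # |z| > 3 against the training scaler counts as extrapolation
            z = (X[:, j] - fs.mean[j]) / fs.std[j]
            if (np.abs(z) > span).any():
                extrapolated.append(name)
        pred = model.predict(X) * 100.0  # fraction -> percent
    else:
        pred = np.array([r.prediction for r in rows])

    report_rows = tuple(
        (r.plant_source, r.digestibility, float(p), percentage_error(r.digestibility, float(p)))
        for r, p in zip(rows, pred)
    )
    metrics = evaluate(measured, pred)
    r = float(np.corrcoef(measured, pred)[0, 1])
    return ValidationReport(rows=report_rows, mae=metrics.mae, rmse=metrics.rmse,
                            r2_pearson_squared=r * r, r2_determination=metrics.r2,
                            extrapolated=tuple(extrapolated))
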