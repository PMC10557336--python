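"""Regression metrics: RMSE, MAE, Pearson R, and residual SD.

SD follows the CASF scoring-power convention: the standard deviation of
the residuals of the experimental affinities about the least-squares line
of affinities on predictions, with an n - 1 denominator.  Like R it is
invariant to affine transformations of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mae: float
    pearson_r: float
    sd_regression: float
    n: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "sd_regression": self.sd_regression,
            "n": self.n,
        }


def compute_metrics(predictions, labels) -> MetricsReport:
    """Compute RMSE / MAE / Pearson R / regression SD.

    Requires equal-length vectors with at least two entries.  When either
    vector has zero variance, R and SD are undefined and reported as NaN.
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    n = pred.size
    if n < 2:
        raise ValueError("need at least two points")

    resid = pred - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))

    if np.std(pred) == 0.0 or np.std(y) == 0.0:
        r = float("nan")
        sd = float("nan")
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
        # least-squares line of labels on predictions: y ~ a + b * pred
        b, a = np.polyfit(pred, y, 1)
        line_resid = y - (a + b * pred)
        sd = float(np.sqrt(np.sum(line_resid**2) / (n - 1)))
    return MetricsReport(rmse=rmse, mae=mae, pearson_r=r, sd_regression=sd, n=n)
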