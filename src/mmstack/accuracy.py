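"""Prediction-accuracy metrics.

Two fold-wise accuracies are used throughout: Pearson's correlation between
predicted and observed scores, and the coefficient of determination (COD)
``1 - SS_res/SS_tot`` about the observed mean, which can be negative for
worse-than-mean predictors and is the stricter of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import r2_score

METRICS = ("pearson_r", "cod")


@dataclass
class AccuracyRecord:
    model: str
    repeat: int
    fold: int
    pearson_r: float
    cod: float

    def get(self, metric: str) -> float:
        if metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
        return getattr(self, metric)


def _check(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if obs.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(obs) == 0:
        raise ValueError("constant observed vector: accuracy undefined")
    return obs, pred


def pearson_accuracy(observed, predicted) -> float:
    """Pearson correlation; defined as 0 for zero-variance predictions."""
    obs, pred = _check(observed, predicted)
    if np.ptp(pred) == 0:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1])


def cod_accuracy(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    obs, pred = _check(observed, predicted)
    return float(r2_score(obs, pred))


def accuracy_record(model: str, repeat: int, fold: int,
                    observed, predicted) -> AccuracyRecord:
    return AccuracyRecord(model=model, repeat=repeat, fold=fold,
                          pearson_r=pearson_accuracy(observed, predicted),
                          cod=cod_accuracy(observed, predicted))
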