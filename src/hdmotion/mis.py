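"""Continuous Movement Impairment Score (MIS).

A linear epsilon-insensitive SVM regression maps the five most
informative baseline-simple features to the clinician-rated modified
upper-limb motor score (mULMS, 0-20).  The model is fitted on HD
participants only and evaluated by leave-one-out cross-validation; the
MIS is reported on the raw regression scale (not clipped to [0, 20]).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .io_core import FeatureVector, ValidationError

logger = logging.getLogger(__name__)

N_PREDICTORS = 5


@dataclass
class MisModel:
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    coef: np.ndarray  # weights in standardized space
    intercept: float
    C: float
    epsilon: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_names": self.feature_names,
                    "x_mean": self.x_mean.tolist(),
                    "x_sd": self.x_sd.tolist(),
                    "y_mean": self.y_mean,
                    "y_sd": self.y_sd,
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept,
                    "C": self.C,
                    "epsilon": self.epsilon,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "MisModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["feature_names"],
            x_mean=np.array(d["x_mean"]),
            x_sd=np.array(d["x_sd"]),
            y_mean=d["y_mean"],
            y_sd=d["y_sd"],
            coef=np.array(d["coef"]),
            intercept=d["intercept"],
            C=d["C"],
            epsilon=d["epsilon"],
        )


def fit_mis(
    X: pd.DataFrame,
    mulms: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> MisModel:
    """Fit the linear SVR of mULMS on exactly five standardized predictors.

    Targets are standardized too, so ``epsilon`` is in target-SD units.
    """
    if X.shape[1] != N_PREDICTORS:
        raise ValidationError(f"expected {N_PREDICTORS} predictors, got {X.shape[1]}")
    y = np.asarray(mulms, dtype=float)
    if len(y) < N_PREDICTORS + 1:
        raise ValidationError(
            f"need more participants than predictors (> {N_PREDICTORS}) to fit"
        )
    if np.std(y) == 0:
        raise ValidationError("degenerate target: mULMS is constant")
    arr = X.to_numpy(dtype=float)
    x_mean, x_sd = arr.mean(axis=0), arr.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean, y_sd = float(np.mean(y)), float(np.std(y))
    svr = SVR(kernel="linear", C=C, epsilon=epsilon)
    svr.fit((arr - x_mean) / x_sd, (y - y_mean) / y_sd)
    return MisModel(
        feature_names=list(X.columns),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        coef=svr.coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        C=C,
        epsilon=epsilon,
    )


def predict_mis(model: MisModel, features: FeatureVector | dict | pd.Series) -> float:
    """Linear MIS for one participant-task; raw scale, not clipped."""
    if isinstance(features, FeatureVector):
        values = features.values
    elif isinstance(features, pd.Series):
        values = features.to_dict()
    else:
        values = features
    missing = [n for n in model.feature_names if n not in values]
    if missing:
        raise ValidationError(f"missing features for MIS: {missing}")
    x = np.array([values[n] for n in model.feature_names], dtype=float)
    z = (x - model.x_mean) / model.x_sd
    y_std = float(z @ model.coef + model.intercept)
    return y_std * model.y_sd + model.y_mean


def regression_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, p: int = N_PREDICTORS
) -> dict[str, float]:
    """Pearson r, r^2, adjusted r^2, MAE and MAE as a percentage of the
    maximum observed score."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_true)
    if n < 3 or len(y_pred) != n:
        raise ValidationError("need >= 3 paired observations")
    if np.std(y_true) == 0:
        raise ValidationError("correlation undefined for constant y_true")
    r = float(stats.pearsonr(y_true, y_pred)[0]) if np.std(y_pred) > 0 else 0.0
    r2 = r * r
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else float("nan")
    mae = float(np.mean(np.abs(y_true - y_pred)))
    nmae = 100.0 * mae / float(np.max(y_true))
    return {
        "pearson_r": r,
        "r_squared": r2,
        "adj_r_squared": adj_r2,
        "mae": mae,
        "normalized_mae_percent": nmae,
        "n": n,
        "p": p,
    }


@dataclass
class RegressionReport:
    predictions: dict[str, float]
    metrics: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"predictions": self.predictions, "metrics": self.metrics},
                fh,
                indent=2,
            )


def loocv_mis(
    X: pd.DataFrame,
    mulms: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> RegressionReport:
    """Leave-one-out evaluation: n fits, metrics on held-out predictions."""
    y = np.asarray(mulms, dtype=float)
    n = len(y)
    if n < 7:
        raise ValidationError("need >= 7 participants for LOOCV")
    preds = {}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_mis(X.iloc[mask], y[mask], C=C, epsilon=epsilon)
        preds[str(X.index[i])] = predict_mis(model, X.iloc[i])
    y_pred = np.array([preds[str(pid)] for pid in X.index])
    return RegressionReport(
        predictions=preds, metrics=regression_metrics(y, y_pred)
    )
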