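"""The cognitive age model: scaler + linear regression, 5-fold CV, bias
correction, and per-participant Cognitive Age Delta (CAD).

Chronological age is regressed on the z-scored battery within the
biomarker-negative reference group, minimizing mean squared error. Age
models of this kind systematically overpredict young ages and underpredict
old ages (regression to the mean); the bias is estimated by fitting a line
to the *out-of-fold* prediction error (delta = y_hat - y) against age and
subtracting it, yielding a bias-corrected predicted cognitive age. Finally

    CAD = y_hat_corrected - y

so positive CAD means cognition "older" than chronological age. The model
is fitted on the reference group only and applied identically to all groups.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .biomarkers import GROUP_REFERENCE

logger = logging.getLogger(__name__)


def fit_bias_correction(
    predictions: np.ndarray, ages: np.ndarray
) -> tuple[float, float]:
    """OLS of raw delta (prediction - age) on age; returns (slope, intercept).

    Closed-form simple regression; requires >= 3 pairs and non-degenerate
    age variance.
    """
    predictions = np.asarray(predictions, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 3:
        raise ValueError("bias correction needs at least 3 prediction/age pairs")
    if np.var(ages) == 0.0:
        raise ValueError("zero age variance: bias line undefined")
    delta = predictions - ages
    slope = float(np.cov(ages, delta, bias=True)[0, 1] / np.var(ages))
    intercept = float(delta.mean() - slope * ages.mean())
    return slope, intercept


@dataclasses.dataclass
class CognitiveAgeModel:
    """Fitted scaler, regression coefficients and bias line, plus CV record."""

    feature_order: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coefficients: np.ndarray  # years per scaled unit
    intercept: float  # years
    bias_slope: float
    bias_intercept: float
    bias_mode: str  # "delta" or "inverse"
    cv_folds: int
    cv_seed: int
    fold_mse: list[float]
    fit_group: str
    oof_ids: list[str]
    oof_ages: np.ndarray
    oof_predictions: np.ndarray

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return Z @ self.coefficients + self.intercept

    def correct(self, y_hat_raw: np.ndarray, ages: np.ndarray) -> np.ndarray:
        """Remove the age-dependent prediction bias."""
        ages = np.asarray(ages, dtype=float)
        if self.bias_mode == "delta":
            return y_hat_raw - (self.bias_slope * ages + self.bias_intercept)
        # inverse scheme: y_hat ~ k*y + c fitted instead; invert the line
        return (y_hat_raw - self.bias_intercept) / self.bias_slope

    def oof_cad(self) -> pd.DataFrame:
        """Bias-corrected CAD of the fit rows from out-of-fold predictions."""
        corrected = self.correct(self.oof_predictions, self.oof_ages)
        return pd.DataFrame(
            {
                "id": self.oof_ids,
                "y": self.oof_ages,
                "y_hat_raw": self.oof_predictions,
                "y_hat_corrected": corrected,
                "cad": corrected - self.oof_ages,
            }
        )

    def to_dict(self) -> dict:
        return {
            "feature_order": list(self.feature_order),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "bias_slope": self.bias_slope,
            "bias_intercept": self.bias_intercept,
            "bias_mode": self.bias_mode,
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
            "fold_mse": list(self.fold_mse),
            "fit_group": self.fit_group,
            "oof_ids": list(self.oof_ids),
            "oof_ages": self.oof_ages.tolist(),
            "oof_predictions": self.oof_predictions.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CognitiveAgeModel":
        return cls(
            feature_order=list(data["feature_order"]),
            scaler_mean=np.array(data["scaler_mean"], dtype=float),
            scaler_scale=np.array(data["scaler_scale"], dtype=float),
            coefficients=np.array(data["coefficients"], dtype=float),
            intercept=float(data["intercept"]),
            bias_slope=float(data["bias_slope"]),
            bias_intercept=float(data["bias_intercept"]),
            bias_mode=data["bias_mode"],
            cv_folds=int(data["cv_folds"]),
            cv_seed=int(data["cv_seed"]),
            fold_mse=[float(v) for v in data["fold_mse"]],
            fit_group=data["fit_group"],
            oof_ids=list(data["oof_ids"]),
            oof_ages=np.array(data["oof_ages"], dtype=float),
            oof_predictions=np.array(data["oof_predictions"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "CognitiveAgeModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _check_rank(X: np.ndarray, features: list[str]) -> None:
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        corr = np.corrcoef(Xc, rowvar=False)
        dependent = [
            f"{features[i]} ~ {features[j]}"
            for i in range(len(features))
            for j in range(i + 1, len(features))
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        detail = "; ".join(dependent) if dependent else "multi-column dependence"
        raise ValueError(f"rank-deficient design (rank {rank}): {detail}")


def fit_age_model(
    table: pd.DataFrame,
    features: list[str],
    fit_group: str = GROUP_REFERENCE,
    folds: int = 5,
    seed: int = 0,
    group_col: str = "group",
    bias_mode: str = "delta",
    scale_per_fold: bool = False,
) -> CognitiveAgeModel:
    """Fit the cognitive age model on the fit group.

    The feature scaler is estimated once on the full fit sample (optionally
    per fold), out-of-fold predictions are collected under a shuffled,
    seed-controlled K-fold split, the final coefficients are refit on the
    full sample, and the bias line is fitted on the out-of-fold deltas only.
    """
    if bias_mode not in ("delta", "inverse"):
        raise ValueError("bias_mode must be 'delta' or 'inverse'")
    sub = table[table[group_col] == fit_group].dropna(subset=[*features, "age"])
    n = len(sub)
    if n < folds:
        raise ValueError(f"fit group has {n} complete rows, fewer than {folds} folds")
    X = sub[features].to_numpy(dtype=float)
    y = sub["age"].to_numpy(dtype=float)
    _check_rank(X, features)

    scaler = StandardScaler().fit(X)
    if (scaler.scale_ == 0).any():
        constant = [f for f, s in zip(features, scaler.scale_) if s == 0]
        raise ValueError(f"constant feature(s) in fit sample: {constant}")
    Z = scaler.transform(X)

    kfold = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(n)
    fold_mse: list[float] = []
    for train_idx, test_idx in kfold.split(Z):
        if scale_per_fold:
            fold_scaler = StandardScaler().fit(X[train_idx])
            Ztr = fold_scaler.transform(X[train_idx])
            Zte = fold_scaler.transform(X[test_idx])
        else:
            Ztr, Zte = Z[train_idx], Z[test_idx]
        reg = LinearRegression().fit(Ztr, y[train_idx])
        pred = reg.predict(Zte)
        oof[test_idx] = pred
        fold_mse.append(float(np.mean((pred - y[test_idx]) ** 2)))

    final = LinearRegression().fit(Z, y)

    if bias_mode == "delta":
        bias_slope, bias_intercept = fit_bias_correction(oof, y)
    else:
        # regress y_hat on y and later invert the line
        if np.var(y) == 0.0:
            raise ValueError("zero age variance: bias line undefined")
        bias_slope = float(np.cov(y, oof, bias=True)[0, 1] / np.var(y))
        bias_intercept = float(oof.mean() - bias_slope * y.mean())

    return CognitiveAgeModel(
        feature_order=list(features),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        coefficients=final.coef_.copy(),
        intercept=float(final.intercept_),
        bias_slope=bias_slope,
        bias_intercept=bias_intercept,
        bias_mode=bias_mode,
        cv_folds=folds,
        cv_seed=seed,
        fold_mse=fold_mse,
        fit_group=fit_group,
        oof_ids=sub["id"].astype(str).tolist() if "id" in sub else [str(i) for i in sub.index],
        oof_ages=y.copy(),
        oof_predictions=oof,
    )


def predict_cad(
    model: CognitiveAgeModel,
    table: pd.DataFrame,
    group_col: str = "group",
    return_skipped: bool = False,
):
    """Predict CAD for every complete row of ``table``.

    Returns a DataFrame with columns id, group, y, y_hat_raw,
    y_hat_corrected, cad. Rows missing any model feature (or age) are
    skipped and reported; pass ``return_skipped=True`` to also get their ids.
    """
    required = [*model.feature_order, "age"]
    complete = table.dropna(subset=required)
    skipped = table.loc[~table.index.isin(complete.index)]
    skipped_ids = (
        skipped["id"].astype(str).tolist() if "id" in skipped else list(skipped.index)
    )
    if skipped_ids:
        logger.warning(
            "%d row(s) skipped for missing model features: %s",
            len(skipped_ids),
            skipped_ids,
        )
    X = complete[model.feature_order].to_numpy(dtype=float)
    y = complete["age"].to_numpy(dtype=float)
    y_hat_raw = model.predict_raw(X)
    y_hat_corrected = model.correct(y_hat_raw, y)
    out = pd.DataFrame(
        {
            "id": complete["id"].astype(str).to_numpy()
            if "id" in complete
            else complete.index.astype(str),
            "group": complete[group_col].to_numpy()
            if group_col in complete
            else "",
            "y": y,
            "y_hat_raw": y_hat_raw,
            "y_hat_corrected": y_hat_corrected,
            "cad": y_hat_corrected - y,
        }
    )
    if return_skipped:
        return out, skipped_ids
    return out
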