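"""Education residualization of test scores, scale-preserving.

Each selected score X is regressed on years of education within the
reference group; the corrected score is the residual re-centred on the
original mean,

    X_corrected = X_bar + (X - X_hat),

so corrected scores keep their native scale and range while being
orthogonal to education in the fitting sample. The model is fitted on the
biomarker-negative reference group only and applied unchanged to all
groups, so pathology groups cannot distort the normative education effect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import GROUP_REFERENCE

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class EducationCorrection:
    """Closed-form simple OLS of one score on education years."""

    mean: float  # X_bar of the fitting sample
    slope: float  # score units per education year
    intercept: float
    n: int

    def predict(self, education: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(education, dtype=float)


@dataclasses.dataclass
class EducationCorrectionModel:
    corrections: dict[str, EducationCorrection]
    fit_group: str

    def to_dict(self) -> dict:
        return {
            "fit_group": self.fit_group,
            "corrections": {
                k: dataclasses.asdict(v) for k, v in self.corrections.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EducationCorrectionModel":
        return cls(
            corrections={
                k: EducationCorrection(**v) for k, v in data["corrections"].items()
            },
            fit_group=data["fit_group"],
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "EducationCorrectionModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_education_model(
    table: pd.DataFrame,
    features: list[str],
    fit_group: str = GROUP_REFERENCE,
    group_col: str = "group",
    min_n: int = 3,
) -> EducationCorrectionModel:
    """Fit one simple OLS (score ~ education) per feature on the fit group.

    Coefficients are the closed-form covariance/variance solution on rows
    with both the feature and education present.
    """
    sub = table if fit_group is None else table[table[group_col] == fit_group]
    corrections: dict[str, EducationCorrection] = {}
    for feature in features:
        pair = sub[["education", feature]].dropna()
        if len(pair) < min_n:
            raise ValueError(
                f"feature '{feature}': only {len(pair)} complete rows, need >= {min_n}"
            )
        edu = pair["education"].to_numpy(dtype=float)
        x = pair[feature].to_numpy(dtype=float)
        edu_var = np.var(edu)
        if edu_var == 0.0:
            raise ValueError(
                f"feature '{feature}': zero education variance in fit group"
            )
        slope = float(np.cov(edu, x, bias=True)[0, 1] / edu_var)
        mean = float(x.mean())
        intercept = mean - slope * float(edu.mean())
        corrections[feature] = EducationCorrection(
            mean=mean, slope=slope, intercept=intercept, n=len(pair)
        )
    return EducationCorrectionModel(corrections=corrections, fit_group=fit_group)


def apply_correction(
    model: EducationCorrectionModel, table: pd.DataFrame
) -> pd.DataFrame:
    """Replace each modeled feature by X_bar + (X - X_hat); returns a copy.

    All rows — including those outside the fit group — are corrected with
    the fit-group model (no refit). Rows with missing education cannot be
    corrected: their features are set missing and the rows are reported.
    """
    out = table.copy()
    edu = out["education"].to_numpy(dtype=float)
    edu_missing = np.isnan(edu)
    if edu_missing.any():
        flagged = out.loc[edu_missing, "id"].tolist() if "id" in out else list(
            out.index[edu_missing]
        )
        logger.warning(
            "%d row(s) with missing education left uncorrected (features set "
            "missing): %s",
            len(flagged),
            flagged,
        )
    for feature, corr in model.corrections.items():
        if feature not in out.columns:
            continue
        x = out[feature].to_numpy(dtype=float)
        corrected = corr.mean + (x - corr.predict(edu))
        corrected[edu_missing] = np.nan
        out[feature] = corrected
    return out
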