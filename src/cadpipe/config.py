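"""Analysis configuration: biomarker cutoffs, feature lists, factor groups.

Configuration objects are pydantic models so that YAML/JSON config files are
validated at load time rather than failing deep inside the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class BiomarkerCutoffs(BaseModel):
    """CSF and MRI thresholds for A/T/N and vascular positivity.

    The amyloid threshold defaults to the operationally adjusted 580 pg/mL
    (the assay-validated 550 pg/mL plus a 5% confidence margin); the original
    550 can be restored via config. Positivity conventions follow the printed
    inequalities: A+ is strict ``<``, T+/N+ strict ``>``, vascular uses ``>=``
    for both the Fazekas score and the microbleed count.
    """

    abeta_pos_below: float = 580.0
    ptau_pos_above: float = 61.0
    ttau_pos_above: float = 350.0
    fazekas_vpos_at_least: int = 2
    cmb_vpos_at_least: int = 4

    @field_validator(
        "abeta_pos_below",
        "ptau_pos_above",
        "ttau_pos_above",
        "fazekas_vpos_at_least",
        "cmb_vpos_at_least",
    )
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("all biomarker thresholds must be > 0")
        return v


#: Factor groups analysed as separate FDR families, one family per
#: (clinical group x factor group) block.
DEFAULT_FACTOR_GROUPS: dict[str, list[str]] = {
    "cognitive_reserve": [
        "vocabulary",
        "cr_questionnaire",
        "leisure_activities",
    ],
    "sedentarism_physical_activity": [
        "sitting_hours_total",
        "computer_sitting_hours",
        "ipaq_total",
    ],
    "tobacco_alcohol": ["smoker", "alcohol_units_week"],
    "diet": ["mediterranean_diet"],
    "sleep_stress": ["psqi_total"],
}

#: Factor groups always modelled with demographic/genetic covariates
#: (education years, sex, APOE e4 load), e.g. the CSF markers.
DEFAULT_ADJUSTED_FACTOR_GROUPS: dict[str, list[str]] = {
    "csf_markers": ["abeta42", "ptau", "ttau"],
}

DEFAULT_ASSOCIATION_COVARIATES: list[str] = ["sex", "apoe4_load", "education"]


class AnalysisConfig(BaseModel):
    """Knobs for the full CAD pipeline.

    ``selected_features`` may be pinned explicitly; when ``None`` the
    age-sensitivity screen chooses them from ``candidate_features``.
    """

    candidate_features: Optional[list[str]] = None
    selected_features: Optional[list[str]] = None
    must_keep_features: list[str] = Field(default_factory=list)
    factor_groups: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_FACTOR_GROUPS.items()}
    )
    adjusted_factor_groups: dict[str, list[str]] = Field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_ADJUSTED_FACTOR_GROUPS.items()
        }
    )
    association_covariates: list[str] = Field(
        default_factory=lambda: list(DEFAULT_ASSOCIATION_COVARIATES)
    )
    alpha: float = 0.05
    rho_max: float = 0.7
    cv_folds: int = 5
    seed: int = 0
    column_name_map: dict[str, str] = Field(default_factory=dict)
    cutoffs: BiomarkerCutoffs = Field(default_factory=BiomarkerCutoffs)
    #: "delta": regress (raw prediction - age) on age and subtract the line.
    #: "inverse": regress raw prediction on age and invert the line.
    bias_mode: str = "delta"
    #: Residualize features for sex and APOE e4 load in addition to education.
    residualize_sex_apoe: bool = False
    #: Re-estimate the feature scaler inside each CV fold instead of once.
    scale_per_fold: bool = False
    float_precision: int = 12

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v):
        if not 0.0 < v < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        return v

    @field_validator("rho_max")
    @classmethod
    def _rho_half_open(cls, v):
        if not 0.0 < v <= 1.0:
            raise ValueError("rho_max must lie in (0, 1]")
        return v

    @field_validator("cv_folds")
    @classmethod
    def _min_folds(cls, v):
        if v < 2:
            raise ValueError("cv_folds must be >= 2")
        return v

    @model_validator(mode="after")
    def _bias_mode_known(self):
        if self.bias_mode not in ("delta", "inverse"):
            raise ValueError("bias_mode must be 'delta' or 'inverse'")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML or JSON file."""
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            if path.suffix.lower() == ".json":
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        return cls.model_validate(data or {})

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON form, for run manifests."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()
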