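"""Synthetic cohort generator for the CAD pipeline.

Emulates a participant table from a biomarker-stratified study of cognitively
unimpaired adults aged 40-80: demographics, APOE e4 load, CSF amyloid/tau
markers, MRI vascular ratings (Fazekas score, microbleed count), a 12-test
neuropsychological battery with planted age and education effects, and
lifestyle/reserve covariates.

Two properties make the generator useful as a test bed:

* **Group consistency by construction.** Biomarker values are drawn strictly
  on the requested side of every classification cutoff, so applying the
  classifier to a generated table reproduces the requested group labels for
  every row.
* **Planted, recoverable covariate effects.** A covariate's effect on the
  cognitive age gap is expressed *through the test scores*: each affected
  row's scores are shifted by ``age_slope * planted_cad_effect * z(covariate)``
  — i.e. the participant performs like someone ``planted_cad_effect * z``
  years older — so the full pipeline (feature selection, residualization,
  age model, bias correction, association GLM) must run to recover it.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .biomarkers import (
    ALL_GROUPS,
    GROUP_AMYLOID,
    GROUP_REFERENCE,
    GROUP_VASCULAR,
)
from .config import BiomarkerCutoffs
from .io import default_feature_set


class FeatureDef(BaseModel):
    """Affine age/education model for one neuropsychological test score.

    ``score = intercept + age_slope*age + education_slope*education + noise``.
    Timed tests (TMT) have positive age slopes (slower with age); accuracy
    scores have negative ones.
    """

    name: str
    age_slope: float
    education_slope: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 0.0

    @field_validator("noise_sd")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("noise_sd must be >= 0")
        return v


class CovariateDef(BaseModel):
    """A lifestyle/reserve covariate with an optional planted effect on CAD.

    ``planted_cad_effect`` is in delta-years per SD of the covariate; 0 means
    the covariate is pure noise (the null used for type-I error checks).
    ``groups_affected`` limits the effect to a subset of group labels
    (``None`` = all groups).
    """

    name: str
    distribution: str = "normal"  # normal | bernoulli | uniform
    params: dict[str, float] = Field(default_factory=dict)
    planted_cad_effect: float = 0.0
    groups_affected: Optional[list[str]] = None

    @model_validator(mode="after")
    def _check(self):
        if self.distribution not in ("normal", "bernoulli", "uniform"):
            raise ValueError(f"unknown distribution '{self.distribution}'")
        if not math.isfinite(self.planted_cad_effect):
            raise ValueError("planted_cad_effect must be finite")
        if self.distribution == "bernoulli":
            p = self.params.get("p", 0.5)
            if not 0.0 <= p <= 1.0:
                raise ValueError("bernoulli p must lie in [0, 1]")
        return self

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "normal":
            return rng.normal(self.params.get("loc", 0.0), self.params.get("scale", 1.0), n)
        if self.distribution == "bernoulli":
            return (rng.random(n) < self.params.get("p", 0.5)).astype(float)
        lo, hi = self.params.get("low", 0.0), self.params.get("high", 1.0)
        return rng.uniform(lo, hi, n)

    def standardize(self, values: np.ndarray) -> np.ndarray:
        """z-score against the *distribution* (population) moments."""
        if self.distribution == "normal":
            mu, sd = self.params.get("loc", 0.0), self.params.get("scale", 1.0)
        elif self.distribution == "bernoulli":
            p = self.params.get("p", 0.5)
            mu, sd = p, math.sqrt(p * (1.0 - p))
        else:
            lo, hi = self.params.get("low", 0.0), self.params.get("high", 1.0)
            mu, sd = (lo + hi) / 2.0, (hi - lo) / math.sqrt(12.0)
        if sd == 0.0:
            return np.zeros_like(values, dtype=float)
        return (values - mu) / sd


def default_feature_defs() -> list[FeatureDef]:
    """Plausible score models for the 12-test battery.

    Intercepts and slopes are in raw score units chosen to resemble the
    instruments (e.g. Digit Symbol-Coding loses about half a point per year
    of age; TMT-B slows by about 1.2 s/year); noise SDs give per-test
    age-equivalent noise of roughly 11-25 years, so that the pooled 12-test
    model predicts age to a few years — the regime the analysis assumes.
    """
    rows = [
        # name, age_slope, education_slope, intercept, noise_sd
        ("Digit Symbol-Coding", -0.55, 1.00, 95.0, 6.0),
        ("Stroop Color Naming", -0.45, 0.80, 100.0, 6.0),
        ("Stroop Word-Color Interference", -0.40, 0.70, 65.0, 5.0),
        ("15-Objects Test", -0.15, 0.10, 48.0, 2.0),
        ("ROCF Delayed Recall", -0.20, 0.30, 30.0, 3.0),
        ("TMT-A", 0.45, -0.40, 15.0, 6.0),
        ("FCSRT Immediate Total Free Recall", -0.25, 0.20, 42.0, 3.5),
        ("TMT-B", 1.20, -1.00, 40.0, 15.0),
        ("Boston Naming Test", -0.10, 0.25, 56.0, 1.8),
        ("Phonemic Fluency P", -0.12, 0.35, 16.0, 3.0),
        ("FCSRT Immediate Total Recall", -0.12, 0.10, 46.0, 1.6),
        ("Semantic Fluency Animals", -0.17, 0.30, 30.0, 3.0),
    ]
    assert [r[0] for r in rows] == default_feature_set()
    return [
        FeatureDef(
            name=n, age_slope=a, education_slope=e, intercept=i, noise_sd=s
        )
        for n, a, e, i, s in rows
    ]


def default_covariate_defs() -> list[CovariateDef]:
    """Null covariates resembling the study's reserve/lifestyle battery."""
    return [
        CovariateDef(name="vocabulary", params={"loc": 45.0, "scale": 8.0}),
        CovariateDef(name="cr_questionnaire", params={"loc": 14.0, "scale": 5.0}),
        CovariateDef(name="leisure_activities", params={"loc": 30.0, "scale": 8.0}),
        CovariateDef(name="sitting_hours_total", params={"loc": 6.5, "scale": 2.0}),
        CovariateDef(name="computer_sitting_hours", params={"loc": 2.5, "scale": 1.8}),
        CovariateDef(name="ipaq_total", params={"loc": 2500.0, "scale": 1400.0}),
        CovariateDef(name="smoker", distribution="bernoulli", params={"p": 0.18}),
        CovariateDef(name="alcohol_units_week", params={"loc": 4.0, "scale": 4.0}),
        CovariateDef(name="mediterranean_diet", params={"loc": 9.0, "scale": 2.0}),
        CovariateDef(name="psqi_total", params={"loc": 5.0, "scale": 2.5}),
    ]


def _default_education_dist() -> dict[int, float]:
    # Discrete years-of-education distribution, median 14, IQR ~ 12-16.
    return {
        8: 0.05,
        10: 0.10,
        11: 0.05,
        12: 0.20,
        13: 0.05,
        14: 0.20,
        15: 0.05,
        16: 0.15,
        17: 0.05,
        18: 0.05,
        19: 0.02,
        20: 0.03,
    }


class SyntheticCohortSpec(BaseModel):
    """All parameters of a synthetic cohort; a fixed seed gives a
    byte-identical table."""

    n_per_group: dict[str, int] = Field(
        default_factory=lambda: {GROUP_REFERENCE: 140, GROUP_AMYLOID: 23, GROUP_VASCULAR: 14}
    )
    age_range: tuple[float, float] = (40.0, 80.0)
    #: Raise the lower age bound per group; +10 on a uniform range shifts the
    #: mean by ~+5 years, reproducing the older pathology groups.
    group_age_min_shift: dict[str, float] = Field(
        default_factory=lambda: {GROUP_AMYLOID: 10.0, GROUP_VASCULAR: 10.0}
    )
    feature_defs: list[FeatureDef] = Field(default_factory=default_feature_defs)
    education_dist: dict[int, float] = Field(default_factory=_default_education_dist)
    covariate_defs: list[CovariateDef] = Field(default_factory=default_covariate_defs)
    biomarker_noise: dict[str, float] = Field(
        default_factory=lambda: {"abeta42": 150.0, "ptau": 15.0, "ttau": 80.0}
    )
    p_female: float = 0.55
    #: P(apoe4_load = 0/1/2) per group; e4 carriers enriched among CUA+.
    apoe_probs: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: {
            GROUP_REFERENCE: (0.79, 0.19, 0.02),
            GROUP_AMYLOID: (0.52, 0.40, 0.08),
            GROUP_VASCULAR: (0.79, 0.19, 0.02),
        }
    )
    #: Fractions of the amyloid group that are additionally T+ / N+.
    amyloid_tau_pos_rate: float = 0.3
    amyloid_ndg_pos_rate: float = 0.2
    cutoffs: BiomarkerCutoffs = Field(default_factory=BiomarkerCutoffs)
    seed: int = 0

    @field_validator("n_per_group")
    @classmethod
    def _counts(cls, v):
        for group, n in v.items():
            if group not in ALL_GROUPS:
                raise ValueError(f"unknown group label '{group}'")
            if n < 0:
                raise ValueError("group counts must be >= 0")
        return v

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range min must be < max")
        if not self.feature_defs:
            raise ValueError("feature_defs must not be empty")
        probs = np.array(list(self.education_dist.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("education_dist must be a probability distribution")
        return self

    @classmethod
    def from_file(cls, path) -> "SyntheticCohortSpec":
        import json
        from pathlib import Path

        import yaml

        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        return cls.model_validate(data or {})


def _halfnormal(rng: np.random.Generator, scale: float, n: int) -> np.ndarray:
    return np.abs(rng.normal(0.0, scale, n))


def _draw_csf(
    rng: np.random.Generator,
    spec: SyntheticCohortSpec,
    n: int,
    amyloid_pos: np.ndarray,
    tau_pos: np.ndarray,
    ndg_pos: np.ndarray,
) -> dict[str, np.ndarray]:
    """CSF markers strictly on the requested side of each cutoff.

    Values are cutoff +/- a fixed offset +/- a half-normal spread, clipped
    away from zero, so boundary equality can never occur.
    """
    c = spec.cutoffs
    noise = spec.biomarker_noise
    abeta = np.where(
        amyloid_pos,
        np.maximum(c.abeta_pos_below - 20.0 - _halfnormal(rng, noise["abeta42"], n), 150.0),
        c.abeta_pos_below + 20.0 + _halfnormal(rng, noise["abeta42"], n),
    )
    ptau = np.where(
        tau_pos,
        c.ptau_pos_above + 5.0 + _halfnormal(rng, noise["ptau"], n),
        np.maximum(c.ptau_pos_above - 5.0 - _halfnormal(rng, noise["ptau"], n), 8.0),
    )
    ttau = np.where(
        ndg_pos,
        c.ttau_pos_above + 20.0 + _halfnormal(rng, noise["ttau"], n),
        np.maximum(c.ttau_pos_above - 20.0 - _halfnormal(rng, noise["ttau"], n), 80.0),
    )
    return {"abeta42": abeta, "ptau": ptau, "ttau": ttau}


def _draw_vascular(
    rng: np.random.Generator, spec: SyntheticCohortSpec, n: int, vpos: bool
) -> tuple[np.ndarray, np.ndarray]:
    c = spec.cutoffs
    if not vpos:
        fazekas = rng.choice([0, 1], size=n, p=[0.7, 0.3])
        cmb = rng.choice([0, 1, 2, 3], size=n, p=[0.85, 0.09, 0.04, 0.02])
        return fazekas, np.minimum(cmb, c.cmb_vpos_at_least - 1)
    mode = rng.choice(["wmh", "cmb", "both"], size=n, p=[0.6, 0.25, 0.15])
    fazekas = np.where(
        mode != "cmb",
        rng.choice([2, 3], size=n, p=[0.75, 0.25]),
        rng.choice([0, 1], size=n, p=[0.7, 0.3]),
    )
    cmb = np.where(
        mode != "wmh",
        c.cmb_vpos_at_least + rng.poisson(2.0, n),
        rng.choice([0, 1, 2, 3], size=n, p=[0.85, 0.09, 0.04, 0.02]),
    )
    return fazekas, cmb


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Generate one cohort table according to ``spec``.

    Returns a DataFrame with one row per participant: id, requested group
    label, demographics, biomarkers, the feature scores and the covariates.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    next_id = 1
    for group, n in spec.n_per_group.items():
        if group not in ALL_GROUPS:
            raise ValueError(f"unknown group label '{group}'")
        if n == 0:
            continue
        lo, hi = spec.age_range
        lo = lo + spec.group_age_min_shift.get(group, 0.0)
        age = rng.uniform(lo, hi, n)
        education = rng.choice(
            np.array(list(spec.education_dist.keys()), dtype=float),
            size=n,
            p=np.array(list(spec.education_dist.values()), dtype=float),
        )
        sex = np.where(rng.random(n) < spec.p_female, "female", "male")
        apoe = rng.choice(
            [0, 1, 2], size=n, p=spec.apoe_probs.get(group, (0.79, 0.19, 0.02))
        )

        amyloid_pos = np.full(n, group == GROUP_AMYLOID)
        tau_pos = np.zeros(n, dtype=bool)
        ndg_pos = np.zeros(n, dtype=bool)
        if group == GROUP_AMYLOID:
            tau_pos = rng.random(n) < spec.amyloid_tau_pos_rate
            ndg_pos = rng.random(n) < spec.amyloid_ndg_pos_rate
        csf = _draw_csf(rng, spec, n, amyloid_pos, tau_pos, ndg_pos)
        fazekas, cmb = _draw_vascular(rng, spec, n, vpos=group == GROUP_VASCULAR)

        covariates = {}
        cad_shift_years = np.zeros(n)
        for cov in spec.covariate_defs:
            values = cov.draw(rng, n)
            covariates[cov.name] = values
            affected = cov.groups_affected is None or group in cov.groups_affected
            if cov.planted_cad_effect != 0.0 and affected:
                cad_shift_years += cov.planted_cad_effect * cov.standardize(values)

        features = {}
        for fd in spec.feature_defs:
            features[fd.name] = (
                fd.intercept
                + fd.age_slope * (age + cad_shift_years)
                + fd.education_slope * education
                + rng.normal(0.0, fd.noise_sd, n)
            )

        frame = pd.DataFrame(
            {
                "id": [f"S{next_id + i:04d}" for i in range(n)],
                "group": group,
                "age": age,
                "sex": sex,
                "education": education,
                "apoe4_load": apoe,
                "abeta42": csf["abeta42"],
                "ptau": csf["ptau"],
                "ttau": csf["ttau"],
                "fazekas": fazekas,
                "cmb_count": cmb,
                "css": False,
                "ischemic_lesion": False,
                **features,
                **covariates,
            }
        )
        next_id += n
        frames.append(frame)
    if not frames:
        raise ValueError("spec requests an empty cohort")
    return pd.concat(frames, ignore_index=True)


def inject_missingness(
    table: pd.DataFrame,
    feature_names: list[str],
    n_missing: int,
    seed: int,
) -> pd.DataFrame:
    """Blank one randomly chosen feature in exactly ``n_missing`` distinct rows.

    Missingness is completely at random. Returns a copy.
    """
    if n_missing < 0:
        raise ValueError("n_missing must be >= 0")
    if n_missing > len(table):
        raise ValueError("n_missing exceeds the number of rows")
    if not feature_names:
        raise ValueError("feature_names must not be empty")
    out = table.copy()
    if n_missing == 0:
        return out
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(out), size=n_missing, replace=False)
    for row in rows:
        feature = feature_names[rng.integers(len(feature_names))]
        out.iloc[row, out.columns.get_loc(feature)] = np.nan
    return out
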