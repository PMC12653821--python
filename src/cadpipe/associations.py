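"""Group comparisons and grouped GLM association analyses of CAD.

CAD distributions across the clinical groups are compared with tie-corrected
Kruskal-Wallis tests. Factor associations are general linear models
``CAD ~ factor`` fitted per clinical group, with CAD kept in years and every
predictor z-scored, so a beta reads as "delta-years of cognitive age per SD
of the factor". p-values are Benjamini-Hochberg adjusted within each
(clinical group x factor group) family; factors that remain significant are
re-tested with sex, APOE e4 load and education years as covariates
(sensitivity models), which inherit the univariate FDR decision and are
reported with raw p. CSF-marker associations run through the same code path
with those covariates always present.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .biomarkers import ANALYSIS_GROUPS
from .config import AnalysisConfig

logger = logging.getLogger(__name__)

UNIVARIATE = "univariate"
ADJUSTED = "covariate_adjusted"

_SEX_CODES = {"male": 0.0, "female": 1.0, "m": 0.0, "f": 1.0}


@dataclasses.dataclass
class AssociationResult:
    clinical_group: str
    factor_group: str
    factor: str
    n: int
    beta: float  # delta-years per SD of the factor
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float | None  # None for sensitivity models (decision inherited)
    model: str  # "univariate" or "covariate_adjusted"
    significant: bool | None = None


@dataclasses.dataclass
class GroupComparisonResult:
    variable: str
    H: float
    df: int
    p: float
    group_summaries: dict[str, tuple[float, float, float]]  # median, q1, q3


def kruskal_wallis(
    samples: list[np.ndarray],
    group_names: list[str] | None = None,
    variable: str = "",
) -> GroupComparisonResult:
    """Tie-corrected Kruskal-Wallis H across >= 2 groups.

    Degenerate input with all observations identical yields H = 0, p = 1.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least 1 observation")
    names = group_names or [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence at all, by convention
        h_stat, p = 0.0, 1.0
    else:
        h_stat, p = stats.kruskal(*arrays)
    summaries = {
        name: (
            float(np.median(a)),
            float(np.percentile(a, 25)),
            float(np.percentile(a, 75)),
        )
        for name, a in zip(names, arrays)
    }
    return GroupComparisonResult(
        variable=variable,
        H=float(h_stat),
        df=len(arrays) - 1,
        p=float(p),
        group_summaries=summaries,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _encode(series: pd.Series) -> pd.Series:
    """Map a possibly categorical column to numeric (sex/bool aware)."""
    if series.dtype == bool:
        return series.astype(float)
    if series.dtype == object:
        lowered = series.astype(str).str.lower()
        if lowered.dropna().isin(_SEX_CODES).all():
            return lowered.map(_SEX_CODES)
        return pd.to_numeric(series, errors="coerce")
    return series.astype(float)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x - x.mean()) / sd  # sd == 0 -> non-finite, caught by caller


def fit_association(
    cad_table: pd.DataFrame,
    cohort: pd.DataFrame,
    factor: str,
    clinical_group: str,
    covariates: tuple[str, ...] = (),
    factor_group: str = "",
    group_col: str = "group",
) -> AssociationResult:
    """GLM of CAD (years) on the z-scored factor within one clinical group.

    With covariates, these are z-scored and entered additively. Returns the
    factor's coefficient with a two-sided t-test p and 95% CI from the
    t distribution.
    """
    if factor not in cohort.columns:
        raise KeyError(f"unknown factor column '{factor}'")
    merged = cad_table[["id", "cad"]].merge(
        cohort[cohort[group_col] == clinical_group], on="id", how="inner"
    )
    design = pd.DataFrame({"cad": merged["cad"]})
    design[factor] = _encode(merged[factor])
    for cov in covariates:
        if cov not in merged.columns:
            raise KeyError(f"unknown covariate column '{cov}'")
        design[cov] = _encode(merged[cov])
    design = design.dropna()
    n = len(design)
    if n < len(covariates) + 3:
        raise ValueError(
            f"group '{clinical_group}', factor '{factor}': only {n} complete rows"
        )
    predictors = [factor, *covariates]
    X = np.column_stack([_zscore(design[p].to_numpy(dtype=float)) for p in predictors])
    if not np.isfinite(X).all():
        raise ValueError(f"constant factor or covariate in '{factor}' model")
    X = sm.add_constant(X)
    fit = sm.OLS(design["cad"].to_numpy(dtype=float), X).fit()
    idx = 1  # the factor is the first regressor after the constant
    ci = fit.conf_int(alpha=0.05)
    return AssociationResult(
        clinical_group=clinical_group,
        factor_group=factor_group,
        factor=factor,
        n=n,
        beta=float(fit.params[idx]),
        ci_low=float(ci[idx, 0]),
        ci_high=float(ci[idx, 1]),
        p_raw=float(fit.pvalues[idx]),
        p_fdr=None,
        model=ADJUSTED if covariates else UNIVARIATE,
    )


def run_association_suite(
    cad_table: pd.DataFrame,
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
    clinical_groups: tuple[str, ...] = ANALYSIS_GROUPS,
    group_col: str = "group",
) -> list[AssociationResult]:
    """Run every (clinical group x factor group) family of GLMs.

    Univariate models are BH-adjusted within their family; post-FDR
    significant factors are re-fitted with the configured covariates as
    sensitivity models. Unknown or degenerate factor columns are skipped
    with a warning and do not count toward the family size.
    """
    config = config or AnalysisConfig()
    covariates = tuple(config.association_covariates)
    results: list[AssociationResult] = []
    blocks = [
        (name, factors, ())
        for name, factors in config.factor_groups.items()
    ] + [
        (name, factors, covariates)
        for name, factors in config.adjusted_factor_groups.items()
    ]
    for clinical_group in clinical_groups:
        for family_name, factors, base_covs in blocks:
            family: list[AssociationResult] = []
            for factor in factors:
                if factor not in cohort.columns:
                    logger.warning(
                        "factor '%s' not in cohort columns; skipped", factor
                    )
                    continue
                try:
                    res = fit_association(
                        cad_table,
                        cohort,
                        factor,
                        clinical_group,
                        covariates=base_covs,
                        factor_group=family_name,
                        group_col=group_col,
                    )
                except ValueError as exc:
                    logger.warning("skipped: %s", exc)
                    continue
                family.append(res)
            if not family:
                continue
            adjusted = fdr_adjust([r.p_raw for r in family])
            for res, p_fdr in zip(family, adjusted):
                res.p_fdr = float(p_fdr)
                res.significant = bool(p_fdr < config.alpha)
            results.extend(family)
            if base_covs:
                continue  # already covariate-adjusted; no sensitivity step
            for res in family:
                if not res.significant:
                    continue
                try:
                    sens = fit_association(
                        cad_table,
                        cohort,
                        res.factor,
                        clinical_group,
                        covariates=covariates,
                        factor_group=family_name,
                        group_col=group_col,
                    )
                except ValueError as exc:
                    logger.warning("sensitivity model skipped: %s", exc)
                    continue
                sens.significant = res.significant  # inherit the FDR decision
                results.append(sens)
    return results


def compare_groups(
    cad_table: pd.DataFrame,
    clinical_groups: tuple[str, ...] = ANALYSIS_GROUPS,
    value_col: str = "cad",
    group_col: str = "group",
    variable: str = "cad",
) -> GroupComparisonResult:
    """Kruskal-Wallis comparison of a CAD-table column across groups."""
    samples, names = [], []
    for group in clinical_groups:
        values = cad_table.loc[cad_table[group_col] == group, value_col].dropna()
        if len(values) > 0:
            samples.append(values.to_numpy(dtype=float))
            names.append(group)
    return kruskal_wallis(samples, group_names=names, variable=variable)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-format table, one row per group x factor x model (forest-ready)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
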