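"""End-to-end convenience driver: classify -> select -> residualize ->
fit -> predict -> associate, in one call."""

from __future__ import annotations

import dataclasses

import pandas as pd

from .age_model import CognitiveAgeModel, fit_age_model, predict_cad
from .associations import (
    AssociationResult,
    GroupComparisonResult,
    compare_groups,
    run_association_suite,
)
from .biomarkers import ANALYSIS_GROUPS, GROUP_REFERENCE, classify_cohort
from .config import AnalysisConfig
from .features import FeatureSelectionResult, select_features_from_table
from .io import default_feature_set
from .residualize import EducationCorrectionModel, apply_correction, fit_education_model


@dataclasses.dataclass
class PipelineResult:
    cohort: pd.DataFrame  # classified cohort (group labels attached)
    selection: FeatureSelectionResult
    education_model: EducationCorrectionModel
    age_model: CognitiveAgeModel
    cad: pd.DataFrame
    skipped_ids: list[str]
    group_comparison: GroupComparisonResult
    associations: list[AssociationResult]


def run_pipeline(
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
    run_associations: bool = True,
) -> PipelineResult:
    """Run the full CAD analysis on a raw cohort table.

    Group labels are (re)derived from the biomarker columns; feature
    selection, the education correction and the age model are all fitted on
    the biomarker-negative reference group and applied to everyone.
    """
    config = config or AnalysisConfig()
    labeled = classify_cohort(cohort, config.cutoffs)

    candidates = config.candidate_features or [
        f for f in default_feature_set() if f in labeled.columns
    ]
    selection = select_features_from_table(
        labeled,
        candidates,
        group=GROUP_REFERENCE,
        alpha=config.alpha,
        rho_max=config.rho_max,
        must_keep=tuple(config.must_keep_features),
    )
    selected = config.selected_features or selection.selected
    if not selected:
        raise ValueError("no feature passed the age-sensitivity screen")

    education_model = fit_education_model(labeled, selected, GROUP_REFERENCE)
    corrected = apply_correction(education_model, labeled)

    age_model = fit_age_model(
        corrected,
        selected,
        fit_group=GROUP_REFERENCE,
        folds=config.cv_folds,
        seed=config.seed,
        bias_mode=config.bias_mode,
        scale_per_fold=config.scale_per_fold,
    )
    cad, skipped = predict_cad(age_model, corrected, return_skipped=True)
    analysis_cad = cad[cad["group"].isin(ANALYSIS_GROUPS)]
    comparison = compare_groups(analysis_cad)

    associations: list[AssociationResult] = []
    if run_associations:
        associations = run_association_suite(analysis_cad, labeled, config)

    return PipelineResult(
        cohort=labeled,
        selection=selection,
        education_model=education_model,
        age_model=age_model,
        cad=cad,
        skipped_ids=skipped,
        group_comparison=comparison,
        associations=associations,
    )
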