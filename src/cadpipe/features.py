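"""Age-sensitive feature preselection within the biomarker-negative group.

Candidate test scores are screened by their Pearson correlation with
chronological age; those passing Bonferroni correction are kept, then a
greedy pass in descending |r| discards any feature too collinear
(|rho| > rho_max) with an already-kept one.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd
from scipy import stats

from .biomarkers import GROUP_REFERENCE

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class AgeCorrelation:
    name: str
    r: float
    p: float
    n: int


@dataclasses.dataclass
class FeatureSelectionResult:
    """Outcome of the screen: all candidates, the threshold, and decisions."""

    candidates: list[AgeCorrelation]
    bonferroni_alpha: float
    selected: list[str]
    dropped_collinear: list[tuple[str, str, float]]  # (kept, dropped, rho)
    skipped: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidates": [dataclasses.asdict(c) for c in self.candidates],
            "bonferroni_alpha": self.bonferroni_alpha,
            "selected": list(self.selected),
            "dropped_collinear": [
                {"kept": k, "dropped": d, "rho": rho}
                for k, d, rho in self.dropped_collinear
            ],
            "skipped": [{"name": n, "reason": r} for n, r in self.skipped],
        }


def correlate_with_age(
    table: pd.DataFrame,
    feature_names: list[str],
    group: str | None = GROUP_REFERENCE,
    group_col: str = "group",
    min_n: int = 3,
) -> tuple[list[AgeCorrelation], list[tuple[str, str]]]:
    """Pearson r (and two-sided p) between age and each feature.

    Pairwise-complete observations per feature; computed within ``group``
    (pass ``None`` for the whole table). Constant or too-sparse features are
    skipped and reported in the second return value.
    """
    sub = table if group is None else table[table[group_col] == group]
    results: list[AgeCorrelation] = []
    skipped: list[tuple[str, str]] = []
    for name in feature_names:
        if name not in sub.columns:
            skipped.append((name, "column not present"))
            continue
        pair = sub[["age", name]].dropna()
        if len(pair) < min_n:
            skipped.append((name, f"fewer than {min_n} complete pairs"))
            continue
        if pair[name].nunique() == 1:
            skipped.append((name, "constant feature: r undefined"))
            continue
        r, p = stats.pearsonr(pair["age"], pair[name])
        results.append(AgeCorrelation(name, float(r), float(p), len(pair)))
    for name, reason in skipped:
        logger.warning("feature '%s' skipped: %s", name, reason)
    return results, skipped


def compute_rho_matrix(
    table: pd.DataFrame,
    feature_names: list[str],
    group: str | None = GROUP_REFERENCE,
    group_col: str = "group",
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix between features."""
    sub = table if group is None else table[table[group_col] == group]
    present = [f for f in feature_names if f in sub.columns]
    return sub[present].corr(method="pearson")


def select_features(
    correlations: list[AgeCorrelation],
    rho_matrix: pd.DataFrame,
    alpha: float = 0.05,
    rho_max: float = 0.7,
    m_tests: int | None = None,
    must_keep: tuple[str, ...] = (),
) -> FeatureSelectionResult:
    """Bonferroni screen then greedy collinearity pruning.

    Features with raw p below ``alpha / m_tests`` survive the screen
    (``m_tests`` defaults to the number of candidates — one family). The
    survivors are scanned in descending |r| (ties broken by input order);
    a feature is dropped if its |rho| with any already-kept feature exceeds
    ``rho_max``. ``must_keep`` features are retained unconditionally and
    considered first, emulating a curated domain-coverage choice.
    """
    if not correlations:
        raise ValueError("empty candidate list")
    m = m_tests if m_tests is not None else len(correlations)
    if m < len(correlations):
        raise ValueError("m_tests must be >= the number of candidates")
    threshold = alpha / m
    survivors = [c for c in correlations if c.p < threshold]

    order = sorted(
        range(len(survivors)),
        key=lambda i: (survivors[i].name not in must_keep, -abs(survivors[i].r), i),
    )
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for i in order:
        cand = survivors[i]
        blocker = None
        for prev in kept:
            if prev in rho_matrix.index and cand.name in rho_matrix.columns:
                rho = rho_matrix.loc[prev, cand.name]
                if pd.notna(rho) and abs(rho) > rho_max:
                    blocker = (prev, float(rho))
                    break
        if blocker is not None and cand.name not in must_keep:
            dropped.append((blocker[0], cand.name, blocker[1]))
        else:
            kept.append(cand.name)
    return FeatureSelectionResult(
        candidates=correlations,
        bonferroni_alpha=threshold,
        selected=kept,
        dropped_collinear=dropped,
    )


def select_features_from_table(
    table: pd.DataFrame,
    candidate_features: list[str],
    group: str | None = GROUP_REFERENCE,
    alpha: float = 0.05,
    rho_max: float = 0.7,
    m_tests: int | None = None,
    must_keep: tuple[str, ...] = (),
    group_col: str = "group",
) -> FeatureSelectionResult:
    """Convenience wrapper: correlate, build the rho matrix, and select."""
    correlations, skipped = correlate_with_age(
        table, candidate_features, group=group, group_col=group_col
    )
    rho = compute_rho_matrix(
        table, [c.name for c in correlations], group=group, group_col=group_col
    )
    result = select_features(
        correlations, rho, alpha=alpha, rho_max=rho_max, m_tests=m_tests,
        must_keep=must_keep,
    )
    result.skipped = skipped
    return result
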