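"""A/T/N and vascular biomarker classification of cognitively unimpaired adults.

Amyloid (A), tau pathology (T) and neurodegeneration (N) status come from CSF
Aβ42, p-tau and t-tau against fixed assay cutoffs; vascular status (V) from
precomputed MRI ratings (Fazekas white-matter-hyperintensity score and cerebral
microbleed count). Records are then assigned to one of three analysis groups:

- ``CUA-V-`` — biomarker-negative reference group: A−T−N− and V−
- ``CUA+``   — amyloid pathology: A+ (irrespective of T and N) and V−
- ``CUV+``   — vascular pathology: V+ with an otherwise negative ATN profile

Everything else (e.g. A+V+, or isolated T+/N+) falls into ``other``; records
with non-traumatic cortical superficial siderosis or established ischemic
lesions are excluded to ``other`` as well; records whose status cannot be
computed are ``unclassifiable``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import BiomarkerCutoffs

GROUP_REFERENCE = "CUA-V-"
GROUP_AMYLOID = "CUA+"
GROUP_VASCULAR = "CUV+"
GROUP_OTHER = "other"
GROUP_UNCLASSIFIABLE = "unclassifiable"

ANALYSIS_GROUPS: tuple[str, ...] = (GROUP_REFERENCE, GROUP_AMYLOID, GROUP_VASCULAR)
ALL_GROUPS: frozenset[str] = frozenset(
    (*ANALYSIS_GROUPS, GROUP_OTHER, GROUP_UNCLASSIFIABLE)
)


class MissingBiomarkerError(ValueError):
    """Raised when a status cannot be determined from the available markers."""


@dataclass(frozen=True)
class ATNStatus:
    amyloid: bool
    tau: bool
    neurodegeneration: bool

    def __str__(self) -> str:  # e.g. "A+T-N-"
        return (
            f"A{'+' if self.amyloid else '-'}"
            f"T{'+' if self.tau else '-'}"
            f"N{'+' if self.neurodegeneration else '-'}"
        )


def _get(record: Mapping, key: str):
    value = record.get(key) if hasattr(record, "get") else getattr(record, key, None)
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    return value


def atn_status(record: Mapping, cutoffs: BiomarkerCutoffs | None = None) -> ATNStatus:
    """Determine A/T/N status from CSF markers.

    A+ iff abeta42 strictly below the amyloid cutoff; T+ iff ptau strictly
    above the p-tau cutoff; N+ iff ttau strictly above the t-tau cutoff.

    Raises
    ------
    MissingBiomarkerError
        If any of the three CSF markers is missing, naming it.
    """
    cutoffs = cutoffs or BiomarkerCutoffs()
    missing = [k for k in ("abeta42", "ptau", "ttau") if _get(record, k) is None]
    if missing:
        raise MissingBiomarkerError(f"missing CSF marker(s): {', '.join(missing)}")
    return ATNStatus(
        amyloid=float(_get(record, "abeta42")) < cutoffs.abeta_pos_below,
        tau=float(_get(record, "ptau")) > cutoffs.ptau_pos_above,
        neurodegeneration=float(_get(record, "ttau")) > cutoffs.ttau_pos_above,
    )


def vascular_status(record: Mapping, cutoffs: BiomarkerCutoffs | None = None) -> bool:
    """Determine vascular positivity: Fazekas >= 2 or >= 4 microbleeds.

    If one of the two ratings is missing, a positive value on the other is
    still conclusive (V+); a negative one is not, and raises.
    """
    cutoffs = cutoffs or BiomarkerCutoffs()
    fazekas = _get(record, "fazekas")
    cmb = _get(record, "cmb_count")
    if fazekas is None and cmb is None:
        raise MissingBiomarkerError("missing both fazekas and cmb_count")
    positive = False
    if fazekas is not None and float(fazekas) >= cutoffs.fazekas_vpos_at_least:
        positive = True
    if cmb is not None and float(cmb) >= cutoffs.cmb_vpos_at_least:
        positive = True
    if positive:
        return True
    if fazekas is None or cmb is None:
        raise MissingBiomarkerError(
            "one MRI rating missing and the other negative: V- not established"
        )
    return False


def assign_group(record: Mapping, cutoffs: BiomarkerCutoffs | None = None) -> str:
    """Assign a record to CUA-V-, CUA+, CUV+, other, or unclassifiable.

    Records flagged with cortical superficial siderosis (``css``) or an
    established ischemic lesion (``ischemic_lesion``) are excluded to
    ``other`` regardless of biomarker values.
    """
    cutoffs = cutoffs or BiomarkerCutoffs()
    if bool(_get(record, "css")) or bool(_get(record, "ischemic_lesion")):
        return GROUP_OTHER
    try:
        atn = atn_status(record, cutoffs)
        vpos = vascular_status(record, cutoffs)
    except MissingBiomarkerError:
        return GROUP_UNCLASSIFIABLE
    atn_negative = not (atn.amyloid or atn.tau or atn.neurodegeneration)
    if atn_negative and not vpos:
        return GROUP_REFERENCE
    if atn.amyloid and not vpos:
        return GROUP_AMYLOID
    if vpos and atn_negative:
        return GROUP_VASCULAR
    return GROUP_OTHER


def classify_cohort(
    table: pd.DataFrame,
    cutoffs: BiomarkerCutoffs | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Classify every row of a cohort table; returns a copy with status columns.

    Adds ``A``/``T``/``N``/``V`` boolean columns (nullable; pd.NA where the
    underlying markers are missing) and the analysis ``group`` label.
    """
    cutoffs = cutoffs or BiomarkerCutoffs()
    out = table.copy()
    out["A"] = pd.array(out["abeta42"] < cutoffs.abeta_pos_below, dtype="boolean")
    out.loc[out["abeta42"].isna(), "A"] = pd.NA
    out["T"] = pd.array(out["ptau"] > cutoffs.ptau_pos_above, dtype="boolean")
    out.loc[out["ptau"].isna(), "T"] = pd.NA
    out["N"] = pd.array(out["ttau"] > cutoffs.ttau_pos_above, dtype="boolean")
    out.loc[out["ttau"].isna(), "N"] = pd.NA
    labels = [assign_group(row, cutoffs) for row in out.to_dict("records")]
    out[group_col] = labels
    return out
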