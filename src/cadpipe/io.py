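"""Read, validate and write participant tables and pipeline outputs.

The on-disk format is plain CSV (UTF-8, comma-delimited, header row); missing
values are empty cells or ``NA``. Internally missing values are NaN/None,
never sentinel numbers. A cohort can be consumed either as a
:class:`pandas.DataFrame` (the pipeline currency) or as typed
:class:`ParticipantRecord` objects for row-level access.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("id", "age", "sex", "education")

#: Core, non-score columns recognised in a cohort table.
CORE_COLUMNS = (
    "id",
    "group",
    "age",
    "sex",
    "education",
    "apoe4_load",
    "abeta42",
    "ptau",
    "ttau",
    "fazekas",
    "cmb_count",
    "css",
    "ischemic_lesion",
    "A",
    "T",
    "N",
)

_NUMERIC_CORE = (
    "age",
    "education",
    "apoe4_load",
    "abeta42",
    "ptau",
    "ttau",
    "fazekas",
    "cmb_count",
)


class MissingColumnError(ValueError):
    """A mandatory cohort column is absent from the file."""


@dataclasses.dataclass
class ParticipantRecord:
    """One row of the cohort table, with typed core fields.

    ``scores`` holds the neuropsychological test values (missing entries are
    ``None``); ``covariates`` holds everything else (lifestyle, reserve,
    questionnaire variables).
    """

    id: str
    age: float
    sex: str
    education: float
    apoe4_load: Optional[int] = None
    abeta42: Optional[float] = None
    ptau: Optional[float] = None
    ttau: Optional[float] = None
    fazekas: Optional[int] = None
    cmb_count: Optional[int] = None
    scores: dict = dataclasses.field(default_factory=dict)
    covariates: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not self.age > 0:
            raise ValueError(f"participant {self.id}: age must be > 0")
        if self.education is not None and self.education < 0:
            raise ValueError(f"participant {self.id}: education must be >= 0")
        if self.apoe4_load is not None and self.apoe4_load not in (0, 1, 2):
            raise ValueError(f"participant {self.id}: apoe4_load must be 0, 1 or 2")
        if self.cmb_count is not None and self.cmb_count < 0:
            raise ValueError(f"participant {self.id}: cmb_count must be >= 0")


def default_feature_set() -> list[str]:
    """The 12-test neuropsychological battery used for cognitive age modeling.

    Ordered, duplicate-free, and stable across calls: processing speed and
    executive measures first (the most age-sensitive), then memory, language
    and fluency.
    """
    return [
        "Digit Symbol-Coding",
        "Stroop Color Naming",
        "Stroop Word-Color Interference",
        "15-Objects Test",
        "ROCF Delayed Recall",
        "TMT-A",
        "FCSRT Immediate Total Free Recall",
        "TMT-B",
        "Boston Naming Test",
        "Phonemic Fluency P",
        "FCSRT Immediate Total Recall",
        "Semantic Fluency Animals",
    ]


def read_cohort_frame(
    path: str | Path, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Read a cohort CSV into a DataFrame, applying the configured column map.

    Mandatory columns (id, age, sex, education) must be present after
    renaming, otherwise :class:`MissingColumnError` names the first missing
    one. Unparseable numeric cells are coerced to missing and reported (with
    1-based data row numbers) through the logger.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(
        path, na_values=["NA"], keep_default_na=True, float_precision="round_trip"
    )
    if config.column_name_map:
        df = df.rename(columns=config.column_name_map)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"mandatory column missing from {path}: '{col}'")
    bad_cells: list[tuple[int, str, object]] = []
    numeric_cols = [c for c in df.columns if c not in ("id", "sex", "group")]
    for col in numeric_cols:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_missing = coerced.isna() & df[col].notna()
            for idx in df.index[newly_missing]:
                bad_cells.append((int(idx) + 1, col, df.at[idx, col]))
            df[col] = coerced
    for row, col, value in bad_cells:
        logger.warning("row %d: unparseable value %r in column '%s'", row, value, col)
    df["id"] = df["id"].astype(str)
    return df


def _opt(value, cast=float):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return cast(value)


def read_cohort(
    path: str | Path, config: AnalysisConfig | None = None
) -> list[ParticipantRecord]:
    """Read a cohort CSV into typed participant records.

    Rows violating record invariants are skipped and reported with their
    1-based data row number; valid rows are returned.
    """
    config = config or AnalysisConfig()
    df = read_cohort_frame(path, config)
    return frame_to_records(df, config)


def frame_to_records(
    df: pd.DataFrame, config: AnalysisConfig | None = None
) -> list[ParticipantRecord]:
    config = config or AnalysisConfig()
    feature_names = set(
        config.selected_features or config.candidate_features or default_feature_set()
    )
    records: list[ParticipantRecord] = []
    for idx, row in df.iterrows():
        try:
            scores = {
                name: _opt(row[name]) for name in df.columns if name in feature_names
            }
            covariates = {
                name: row[name]
                for name in df.columns
                if name not in feature_names and name not in CORE_COLUMNS
            }
            records.append(
                ParticipantRecord(
                    id=str(row["id"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    education=float(row["education"]),
                    apoe4_load=_opt(row.get("apoe4_load"), int),
                    abeta42=_opt(row.get("abeta42")),
                    ptau=_opt(row.get("ptau")),
                    ttau=_opt(row.get("ttau")),
                    fazekas=_opt(row.get("fazekas"), int),
                    cmb_count=_opt(row.get("cmb_count"), int),
                    scores=scores,
                    covariates=covariates,
                )
            )
        except (ValueError, TypeError) as exc:
            logger.error("row %d rejected: %s", int(idx) + 1, exc)
    return records


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "age": rec.age,
            "sex": rec.sex,
            "education": rec.education,
            "apoe4_load": rec.apoe4_load,
            "abeta42": rec.abeta42,
            "ptau": rec.ptau,
            "ttau": rec.ttau,
            "fazekas": rec.fazekas,
            "cmb_count": rec.cmb_count,
        }
        row.update(rec.scores)
        row.update(rec.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort (or any pipeline result table) as UTF-8 CSV."""
    df.to_csv(path, index=False, na_rep="")


def write_manifest(
    path: str | Path,
    config: AnalysisConfig,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Write a JSON run manifest (config hash, seed, package version)."""
    manifest = {
        "cadpipe_version": __version__,
        "config_sha256": config.content_hash(),
        "seed": seed,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
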