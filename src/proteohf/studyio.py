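"""Reading, validation and limit-of-detection filtering of study tables.

The on-disk study is three CSV files: a subject table (one row per
participant in the matched cohort), a protein matrix (subjects x assays,
log2-normalized expression) and an assay metadata table (assay, panel,
LOD on the same log2 scale).  Values below the LOD are extrapolated by
the platform, not missing, so the filter works from the LOD threshold
rather than from missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class StudyValidationError(ValueError):
    """The study tables are inconsistent or malformed."""


REQUIRED_SUBJECT_COLS = ("subject_id", "is_case", "age", "sex", "surgery", "duration")


@dataclass
class Study:
    """In-memory study: aligned subject table, matrix and assay metadata."""

    subjects: pd.DataFrame
    matrix: pd.DataFrame  # index = subject_id, columns = assay names
    assay_meta: pd.DataFrame  # columns: assay, panel, lod


def load_study(subject_path, matrix_path, meta_path) -> Study:
    """Load and cross-validate the three study tables.

    Matrix rows are re-ordered to the subject-table order.  Raises
    :class:`StudyValidationError` naming the offending column/identifier
    on missing columns, duplicate identifiers, unknown subjects,
    non-numeric expression, or assays without metadata.
    """
    subjects = pd.read_csv(subject_path)
    try:
        matrix = pd.read_csv(matrix_path, index_col="subject_id")
    except ValueError as exc:
        raise StudyValidationError(
            f"matrix lacks a 'subject_id' column: {exc}"
        ) from exc
    meta = pd.read_csv(meta_path)

    missing = [c for c in REQUIRED_SUBJECT_COLS if c not in subjects.columns]
    if missing:
        raise StudyValidationError(f"subject table missing columns: {missing}")
    for col in ("assay", "panel", "lod"):
        if col not in meta.columns:
            raise StudyValidationError(f"assay metadata missing column: {col!r}")

    if subjects["subject_id"].duplicated().any():
        dup = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise StudyValidationError(f"duplicate subject id in subject table: {dup!r}")
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise StudyValidationError(f"duplicate subject id in matrix: {dup!r}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise StudyValidationError(f"duplicate assay in matrix: {dup!r}")

    unknown = matrix.index.difference(subjects["subject_id"])
    if len(unknown):
        raise StudyValidationError(
            f"matrix subject(s) absent from subject table: {list(unknown[:5])}"
        )

    non_numeric = [c for c in matrix.columns
                   if not np.issubdtype(matrix[c].dtype, np.number)]
    if non_numeric:
        raise StudyValidationError(
            f"non-numeric expression values in assay(s): {non_numeric[:5]}"
        )

    meta_assays = pd.Index(meta["assay"])
    if meta_assays.duplicated().any():
        dup = meta_assays[meta_assays.duplicated()][0]
        raise StudyValidationError(f"duplicate assay in metadata: {dup!r}")
    without_meta = matrix.columns.difference(meta_assays)
    if len(without_meta):
        raise StudyValidationError(
            f"assay(s) without metadata: {list(without_meta[:5])}"
        )

    # align matrix rows to the subject table; keep only subjects with samples
    have = subjects["subject_id"].isin(matrix.index)
    matrix = matrix.loc[subjects.loc[have, "subject_id"]]
    meta = (
        meta.set_index("assay").loc[matrix.columns]
        .rename_axis("assay").reset_index()
    )
    return Study(subjects=subjects, matrix=matrix, assay_meta=meta)


def filter_by_lod(
    matrix: pd.DataFrame,
    assay_meta: pd.DataFrame,
    max_below_fraction: float = 0.80,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop assays whose values are mostly below the limit of detection.

    An assay is retained iff the fraction of its non-missing values
    strictly below its LOD is <= ``max_below_fraction`` (the exclusion
    rule is strictly ">80% below"; a value exactly at the LOD counts as
    detected).  An assay with no non-missing values at all is excluded
    with reason ``all_missing``.

    Returns ``(filtered_matrix, exclusions)`` where ``exclusions`` has
    columns ``assay``, ``below_lod_fraction``, ``reason``.
    """
    if not 0.0 <= max_below_fraction <= 1.0:
        raise ValueError("max_below_fraction must be in [0, 1]")
    lod = assay_meta.set_index("assay")["lod"]
    without = matrix.columns.difference(lod.index)
    if len(without):
        raise StudyValidationError(f"assay(s) lacking an LOD: {list(without[:5])}")
    if lod.loc[matrix.columns].isna().any():
        bad = lod.loc[matrix.columns][lod.loc[matrix.columns].isna()].index[0]
        raise StudyValidationError(f"assay lacking an LOD: {bad!r}")

    n_obs = matrix.notna().sum(axis=0)
    below = matrix.lt(lod.loc[matrix.columns], axis=1).sum(axis=0)
    frac = below / n_obs.where(n_obs > 0)

    all_missing = n_obs == 0
    too_low = frac > max_below_fraction
    drop = all_missing | too_low.fillna(False)

    exclusions = pd.DataFrame(
        {
            "assay": matrix.columns[drop],
            "below_lod_fraction": frac[drop].to_numpy(),
            "reason": np.where(all_missing[drop], "all_missing", "below_lod"),
        }
    ).reset_index(drop=True)
    return matrix.loc[:, ~drop], exclusions
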