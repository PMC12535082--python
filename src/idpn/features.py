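"""Canonical feature set and feature-table conventions.

The method operates on 17 psychometric features per respondent: the two
Zung standard scores (anxiety, depression), the five NEO-FFI personality
dimensions, and the ten Family Environment Scale dimensions.  A *feature
table* is a pandas DataFrame with one row per respondent, a
``respondent_id`` column, the 17 feature columns in canonical order, and
the NSSI columns ``nssi_flag`` (bool) and ``nssi_severity`` (int).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

FEATURE_NAMES: tuple[str, ...] = (
    "SAS",
    "SDS",
    "Neuroticism",
    "Extraversion",
    "Openness",
    "Agreeableness",
    "Conscientiousness",
    "Cohesion",
    "Expressiveness",
    "Conflict",
    "Independence",
    "Achievement Orientation",
    "Intellectual-Cultural Orientation",
    "Active-Recreational Orientation",
    "Moral-Religious Emphasis",
    "Organization",
    "Control",
)

N_FEATURES = len(FEATURE_NAMES)

ID_COL = "respondent_id"
FLAG_COL = "nssi_flag"
SEVERITY_COL = "nssi_severity"


def edge_list(feature_names: tuple[str, ...] = FEATURE_NAMES) -> list[tuple[int, int]]:
    """All unique unordered feature pairs (i < j); 17 features give 136 edges."""
    p = len(feature_names)
    return list(itertools.combinations(range(p), 2))


def n_edges(p: int = N_FEATURES) -> int:
    return p * (p - 1) // 2


def edge_name(i: int, j: int, feature_names: tuple[str, ...] = FEATURE_NAMES) -> str:
    return f"{feature_names[i]}-{feature_names[j]}"


def validate_feature_table(
    table: pd.DataFrame,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Check a feature table against the canonical schema.

    Columns are matched by name, never by position.  Unknown feature-like
    columns are left alone; missing canonical columns raise.  Rows with any
    missing feature value are dropped with a warning (profiles admitted to
    network construction must be complete; no imputation is performed).
    """
    missing_cols = [c for c in (ID_COL, *feature_names) if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table is missing columns: {missing_cols}")
    out = table.copy()
    if FLAG_COL not in out.columns:
        out[FLAG_COL] = False
    if SEVERITY_COL not in out.columns:
        out[SEVERITY_COL] = 0
    if out[ID_COL].duplicated().any():
        dups = out.loc[out[ID_COL].duplicated(), ID_COL].tolist()
        raise ValueError(f"duplicate respondent ids: {dups[:5]}")
    incomplete = out[list(feature_names)].isna().any(axis=1)
    if incomplete.any():
        if not drop_incomplete:
            raise ValueError(
                f"{int(incomplete.sum())} profiles have missing features"
            )
        warnings.warn(
            f"dropping {int(incomplete.sum())} profiles with missing features "
            f"(ids: {out.loc[incomplete, ID_COL].tolist()[:5]} ...)",
            stacklevel=2,
        )
        out = out.loc[~incomplete]
    ordered = [ID_COL, *feature_names, FLAG_COL, SEVERITY_COL]
    return out[ordered].reset_index(drop=True)


def feature_matrix(
    table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> np.ndarray:
    """Respondents x features float matrix in canonical column order."""
    return table[list(feature_names)].to_numpy(dtype=float)
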