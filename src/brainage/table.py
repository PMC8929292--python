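"""The subject-by-feature table: data model, validation, CSV round-trip.

A :class:`FeatureTable` is a thin, validated wrapper around a pandas
DataFrame with one row per subject: the demographics columns
``subject_id`` (unique strings), ``group`` (``NC``/``SZ``), ``age`` (years),
``gender`` ({0,1}) and optionally ``education`` (years), followed by
regional feature columns named per the :mod:`brainage.atlas` convention.

CSV is the exchange format: UTF-8, comma-separated, '.' decimal, mandatory
header, floats written with 17 significant digits so write -> read is the
identity on valid tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import MODALITIES, parse_feature_name

__all__ = [
    "FeatureTable",
    "TableValidationError",
    "DEMOGRAPHIC_COLUMNS",
    "GROUPS",
    "read_feature_table",
    "write_feature_table",
    "subset_modalities",
]

DEMOGRAPHIC_COLUMNS = ("subject_id", "group", "age", "gender")
OPTIONAL_DEMOGRAPHICS = ("education",)
GROUPS = ("NC", "SZ")


class TableValidationError(ValueError):
    """A feature table violated the data-model contract."""


def _canonical_feature_sort_key(name: str):
    mod, index, rid = parse_feature_name(name)
    from .atlas import MODALITY_INDICES

    return (MODALITIES.index(mod), MODALITY_INDICES[mod].index(index), rid)


@dataclass(frozen=True)
class FeatureTable:
    """Validated cohort table: demographics + named regional features."""

    df: pd.DataFrame
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        _validate(self.df, self.feature_names)

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, expected_names: Sequence[str] | None = None
    ) -> "FeatureTable":
        """Build from a raw DataFrame, inferring and canonically ordering
        the feature columns (every non-demographic column is a feature)."""
        cols = list(df.columns)
        missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in cols]
        if missing:
            raise TableValidationError(f"missing demographics column(s): {missing}")
        features = [
            c for c in cols if c not in DEMOGRAPHIC_COLUMNS + OPTIONAL_DEMOGRAPHICS
        ]
        if expected_names is not None:
            if set(features) != set(expected_names):
                extra = sorted(set(features) - set(expected_names))[:5]
                absent = sorted(set(expected_names) - set(features))[:5]
                raise TableValidationError(
                    f"feature columns do not match the expected name list "
                    f"(unexpected: {extra}..., missing: {absent}...)"
                )
        ordered = sorted(features, key=_canonical_feature_sort_key)
        demo = [c for c in DEMOGRAPHIC_COLUMNS + OPTIONAL_DEMOGRAPHICS if c in cols]
        out = df.loc[:, demo + ordered].reset_index(drop=True)
        # normalize dtypes so the CSV round-trip is the identity
        out["subject_id"] = out["subject_id"].astype(str)
        out["age"] = out["age"].astype(float)
        out["gender"] = out["gender"].astype(int)
        if "education" in out.columns:
            out["education"] = out["education"].astype(float)
        out[ordered] = out[ordered].astype(float)
        return cls(out, tuple(ordered))

    # ---- accessors ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> pd.Series:
        return self.df["subject_id"]

    @property
    def age(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=float)

    @property
    def gender(self) -> np.ndarray:
        return self.df["gender"].to_numpy(dtype=float)

    @property
    def group(self) -> pd.Series:
        return self.df["group"]

    def features(self) -> pd.DataFrame:
        """Feature block, canonical column order."""
        return self.df.loc[:, list(self.feature_names)]

    def values(self) -> np.ndarray:
        return self.features().to_numpy(dtype=float)

    def select_group(self, group: str) -> "FeatureTable":
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        sub = self.df[self.df["group"] == group].reset_index(drop=True)
        return FeatureTable(sub, self.feature_names)

    def select_rows(self, mask_or_index) -> "FeatureTable":
        sub = self.df.loc[mask_or_index].reset_index(drop=True)
        return FeatureTable(sub, self.feature_names)

    def with_features(self, values: np.ndarray) -> "FeatureTable":
        """Same demographics, replaced feature block (shape must match)."""
        if values.shape != (self.n_subjects, len(self.feature_names)):
            raise ValueError(
                f"replacement feature block has shape {values.shape}, expected "
                f"{(self.n_subjects, len(self.feature_names))}"
            )
        out = self.df.copy()
        out.loc[:, list(self.feature_names)] = values
        return FeatureTable(out, self.feature_names)


def _validate(df: pd.DataFrame, feature_names: Iterable[str]) -> None:
    feature_names = tuple(feature_names)
    for col in DEMOGRAPHIC_COLUMNS:
        if col not in df.columns:
            raise TableValidationError(f"missing demographics column {col!r}")
    ids = df["subject_id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise TableValidationError(
            f"duplicate subject id(s): {sorted(set(dup))[:5]}"
        )
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise TableValidationError(f"unknown group label(s): {sorted(bad_group)}")
    bad_gender = set(df["gender"].tolist()) - {0, 1}
    if bad_gender:
        raise TableValidationError(f"gender must be coded 0/1, got {sorted(bad_gender)}")
    if not np.isfinite(df["age"].to_numpy(dtype=float)).all():
        raise TableValidationError("non-finite age value")
    if len(set(feature_names)) != len(feature_names):
        raise TableValidationError("duplicate feature names")
    for name in feature_names:
        parse_feature_name(name)  # raises on convention violation
        if name not in df.columns:
            raise TableValidationError(f"feature column {name!r} absent from table")
    if feature_names:
        block = df.loc[:, list(feature_names)].to_numpy(dtype=float)
        if not np.isfinite(block).all():
            i, j = np.argwhere(~np.isfinite(block))[0]
            raise TableValidationError(
                f"non-finite feature value at row {i} "
                f"(subject {df['subject_id'].iloc[i]!r}), column "
                f"{feature_names[j]!r}"
            )


# ---- CSV I/O ----------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write as UTF-8 CSV with 17-significant-digit floats (round-trip safe)."""
    table.df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_feature_table(
    path: str | Path, expected_names: Sequence[str] | None = None
) -> FeatureTable:
    """Read and validate a cohort CSV.

    Raises :class:`TableValidationError` on missing demographics, duplicate
    subject ids, non-finite values, feature-name convention violations, or
    a mismatch against ``expected_names``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, encoding="utf-8")
    return FeatureTable.from_dataframe(df, expected_names=expected_names)


def subset_modalities(table: FeatureTable, modalities) -> FeatureTable:
    """Keep demographics plus only the requested modalities' features."""
    from .atlas import _check_modalities

    mods = _check_modalities(modalities)  # raises on empty/unknown
    keep = [n for n in table.feature_names if n.split(":", 1)[0] in mods]
    if not keep:
        raise TableValidationError(
            f"table has no features for modalities {mods}"
        )
    demo = [
        c
        for c in DEMOGRAPHIC_COLUMNS + OPTIONAL_DEMOGRAPHICS
        if c in table.df.columns
    ]
    return FeatureTable(table.df.loc[:, demo + keep].copy(), tuple(keep))
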