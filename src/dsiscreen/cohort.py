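"""Labeled subject-by-feature cohort table with explicit missingness.

The cohort is the unit every stage operates on: a matrix of scalar
measurements (demographics, vascular factors, cognitive composites, APOE
carrier status, ICV-normalized regional volumes, a visual MTA rating and an
AD-signature cortical thickness), one binary amyloid-status label per
subject, and a declared kind (continuous / binary / ordinal) per feature.
Feature kinds are metadata, never inferred from the values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LABEL_COLUMN = "amyloid_status"

VALID_KINDS = frozenset({"continuous", "binary", "ordinal"})


class CohortError(ValueError):
    """Raised for malformed cohort tables or files."""


@dataclass
class CohortTable:
    """Subject x feature matrix with a binary amyloid-status label.

    Parameters
    ----------
    data:
        Feature values, indexed by subject id; NaN marks a missing cell.
    labels:
        0 (amyloid negative) / 1 (amyloid positive), aligned with ``data``.
    feature_kinds:
        Mapping feature name -> "continuous" | "binary" | "ordinal".
    """

    data: pd.DataFrame
    labels: pd.Series
    feature_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) != len(self.labels):
            raise CohortError("data and labels have different lengths")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise CohortError(f"duplicate subject ids: {dupes}")
        bad = set(pd.unique(self.labels.dropna())) - {0, 1}
        if bad:
            raise CohortError(f"labels must be 0/1, found {sorted(bad)}")
        self.labels = self.labels.astype(int)
        for name in self.data.columns:
            kind = self.feature_kinds.get(name)
            if kind is None:
                raise CohortError(f"feature {name!r} has no declared kind")
            if kind not in VALID_KINDS:
                raise CohortError(f"feature {name!r} has unknown kind {kind!r}")

    # -- basic views ------------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    def class_values(self, feature: str, label: int) -> np.ndarray:
        """Non-missing values of ``feature`` in the given class."""
        col = self.data.loc[self.labels.values == label, feature]
        return col.dropna().to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Row subset by boolean mask or integer positions."""
        mask = np.asarray(mask)
        return CohortTable(
            data=self.data.iloc[mask] if mask.dtype.kind in "iu" else self.data.loc[mask],
            labels=self.labels.iloc[mask] if mask.dtype.kind in "iu" else self.labels.loc[mask],
            feature_kinds=dict(self.feature_kinds),
        )

    def select_features(self, names: list[str]) -> "CohortTable":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise CohortError(f"features not in cohort: {missing}")
        return CohortTable(
            data=self.data[names].copy(),
            labels=self.labels.copy(),
            feature_kinds={n: self.feature_kinds[n] for n in names},
        )

    def missing_counts(self) -> pd.Series:
        return self.data.isna().sum()

    # -- I/O --------------------------------------------------------------

    def write_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        """Write the cohort as CSV plus a JSON sidecar declaring feature kinds.

        The CSV has one row per subject, a ``subject_id`` column, the
        ``amyloid_status`` label column (0/1) and one column per feature;
        missing cells are written empty.
        """
        path = Path(path)
        out = self.data.copy()
        out.insert(0, LABEL_COLUMN, self.labels.values)
        out.index.name = "subject_id"
        out.to_csv(path)
        schema_path = Path(schema_path) if schema_path else path.with_suffix(".schema.json")
        schema_path.write_text(
            json.dumps({"feature_kinds": self.feature_kinds}, indent=2, sort_keys=True) + "\n"
        )


def read_cohort_csv(
    path: str | Path,
    schema: dict[str, str] | str | Path | None = None,
) -> CohortTable:
    """Read a cohort CSV written by :meth:`CohortTable.write_csv`.

    ``schema`` maps feature name -> kind; it may also be a path to the JSON
    sidecar. When omitted, the default sidecar ``<path>.schema.json`` next to
    the CSV is required — kinds are never guessed from the data.
    """
    path = Path(path)
    if schema is None:
        schema = path.with_suffix(".schema.json")
    if isinstance(schema, (str, Path)):
        schema_file = Path(schema)
        if not schema_file.exists():
            raise CohortError(f"feature-kind schema not found: {schema_file}")
        schema = json.loads(schema_file.read_text())["feature_kinds"]

    frame = pd.read_csv(path, index_col="subject_id")
    if LABEL_COLUMN not in frame.columns:
        raise CohortError(f"missing label column {LABEL_COLUMN!r}")
    labels = frame[LABEL_COLUMN]
    bad = set(pd.unique(labels.dropna())) - {0, 1}
    if bad:
        raise CohortError(f"label column contains values other than 0/1: {sorted(bad)}")
    if labels.isna().any():
        raise CohortError("label column contains missing values")
    data = frame.drop(columns=[LABEL_COLUMN]).astype(float)
    undeclared = [c for c in data.columns if c not in schema]
    if undeclared:
        raise CohortError(f"features without declared kind: {undeclared}")
    return CohortTable(data=data, labels=labels.astype(int), feature_kinds=dict(schema))
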