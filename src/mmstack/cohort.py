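"""Cohort tables and feature blocks.

A cohort is a per-subject table of identifiers, confounding variables and
psychometric targets.  A feature block is one named subjects x features
matrix from a single derivation (e.g. the Fisher-z vectorised upper triangle
of a functional-connectivity matrix), the unit of multimodal integration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Confounding variables present in every cohort, in canonical column order.
CONFOUND_COLUMNS = (
    "age",
    "age2",
    "gender",
    "age_x_gender",
    "age2_x_gender",
    "handedness",
    "brain_size",
    "icv",
)

#: Columns a cohort table must carry besides targets.
BASE_COLUMNS = ("subject_id", "family_id", "age", "gender", "handedness",
                "brain_size", "icv")

MODALITY_TAGS = ("rest", "task", "struct", "diff", "confound")
SHAPE_KINDS = ("connectivity_vector", "region_map")


class CohortValidationError(ValueError):
    """Raised when a cohort table or feature block violates its contract."""


@dataclass
class CohortTable:
    """Per-subject identifiers, confounds and psychometric targets.

    Parameters
    ----------
    table
        One row per subject with columns ``subject_id``, ``family_id``,
        ``age``, ``gender`` (1=female, 2=male), ``handedness`` (in
        [-100, 100]), ``brain_size``, ``icv``; every remaining numeric
        column is treated as a psychometric target.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in BASE_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"cohort table missing columns {missing}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise CohortValidationError(f"duplicate subject_id {dup!r}")
        numeric = df.drop(columns=["subject_id", "family_id"])
        if numeric.isna().any().any():
            col = numeric.columns[numeric.isna().any()][0]
            row = int(numeric.index[numeric[col].isna()][0])
            raise CohortValidationError(
                f"missing value in column {col!r} at row {row}")
        bad_gender = ~df["gender"].isin([1, 2])
        if bad_gender.any():
            row = int(df.index[bad_gender][0])
            raise CohortValidationError(
                f"gender must be coded 1 (female) or 2 (male); "
                f"row {row} has {df['gender'].iloc[row]!r}")
        if (df["icv"] <= 0).any() or (df["brain_size"] <= 0).any():
            raise CohortValidationError("icv and brain_size must be positive")
        self.table = df.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    @property
    def family_ids(self) -> np.ndarray:
        return self.table["family_id"].to_numpy()

    @property
    def target_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in BASE_COLUMNS]

    def target(self, name: str) -> np.ndarray:
        if name not in self.target_names:
            raise KeyError(f"unknown target {name!r}; have {self.target_names}")
        return self.table[name].to_numpy(dtype=float)

    def confound_matrix(self) -> np.ndarray:
        """Return the N x 8 confound design in canonical column order.

        Columns: age, age^2, gender, age*gender, age^2*gender, handedness,
        brain size, ICV.  Gender is coded 1=female, 2=male.
        """
        t = self.table
        age = t["age"].to_numpy(dtype=float)
        gender = t["gender"].to_numpy(dtype=float)
        cols = [
            age,
            age ** 2,
            gender,
            age * gender,
            age ** 2 * gender,
            t["handedness"].to_numpy(dtype=float),
            t["brain_size"].to_numpy(dtype=float),
            t["icv"].to_numpy(dtype=float),
        ]
        return np.column_stack(cols)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str,
                                                "family_id": str})
        return cls(df)


@dataclass
class FeatureBlock:
    """One feature type: a subjects x P matrix with modality metadata."""

    name: str
    matrix: np.ndarray
    modality_tag: str = "rest"
    shape_kind: str = "region_map"
    region_count: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise CohortValidationError(
                f"block {self.name!r}: matrix must be 2-D")
        if self.modality_tag not in MODALITY_TAGS:
            raise CohortValidationError(
                f"block {self.name!r}: modality_tag {self.modality_tag!r} "
                f"not in {MODALITY_TAGS}")
        if self.shape_kind not in SHAPE_KINDS:
            raise CohortValidationError(
                f"block {self.name!r}: shape_kind {self.shape_kind!r} "
                f"not in {SHAPE_KINDS}")
        if not np.isfinite(self.matrix).all():
            i, j = np.argwhere(~np.isfinite(self.matrix))[0]
            raise CohortValidationError(
                f"block {self.name!r}: non-finite value at row {i}, column {j}")
        if self.shape_kind == "connectivity_vector":
            if self.region_count is None:
                raise CohortValidationError(
                    f"block {self.name!r}: connectivity_vector needs region_count")
            r = self.region_count
            expected = r * (r - 1) // 2
            if self.matrix.shape[1] != expected:
                raise CohortValidationError(
                    f"block {self.name!r}: expected {expected} columns "
                    f"(= {r}*({r}-1)/2), got {self.matrix.shape[1]}")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a JSON metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.matrix, delimiter="\t", fmt="%.17g")
        sidecar = {
            "name": self.name,
            "modality_tag": self.modality_tag,
            "shape_kind": self.shape_kind,
            "region_count": self.region_count,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureBlock":
        path = Path(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise CohortValidationError(f"missing sidecar {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(name=meta["name"], matrix=matrix,
                   modality_tag=meta["modality_tag"],
                   shape_kind=meta["shape_kind"],
                   region_count=meta.get("region_count"))


def check_alignment(cohort: CohortTable, blocks: list[FeatureBlock]) -> None:
    """Raise unless every block has exactly one row per cohort subject."""
    n = cohort.n_subjects
    for b in blocks:
        if b.matrix.shape[0] != n:
            raise CohortValidationError(
                f"block {b.name!r} has {b.matrix.shape[0]} rows, "
                f"cohort has {n} subjects; refusing to reindex silently")
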