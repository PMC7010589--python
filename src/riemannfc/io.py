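"""Plain-text I/O: per-subject connectivity matrices and phenotype tables.

Connectivity matrices are stored one subject per file as whitespace-delimited
text (k rows of k floats, 12 significant digits — lossless for a write/read
round trip at that precision).  Phenotypes are a CSV with mandatory columns
``subject_id, group, age, sex`` and an optional severity column
(``ybocs_total``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix

__all__ = [
    "CohortTable",
    "read_matrices",
    "write_matrices",
    "read_phenotypes",
    "write_phenotypes",
]

REQUIRED_PHENOTYPE_COLUMNS = ("subject_id", "group", "age", "sex")
SEVERITY_COLUMN = "ybocs_total"


@dataclass(frozen=True)
class CohortTable:
    """Validated phenotype table: one row per subject.

    Columns: ``subject_id`` (unique), ``group`` (exactly two levels, e.g.
    patient/control), ``age``, ``sex``, and optionally ``ybocs_total``
    (symptom-severity score).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True)
        for col in REQUIRED_PHENOTYPE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"phenotype table is missing column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        levels = sorted(df["group"].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(
                f"group must have exactly two levels, found {levels}"
            )
        object.__setattr__(self, "table", df)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def group_levels(self) -> tuple[str, str]:
        return tuple(sorted(self.table["group"].astype(str).unique()))

    def indicator(self, positive_label: str = "patient") -> np.ndarray:
        """0/1 label vector, 1 for rows whose group == positive_label."""
        groups = self.table["group"].astype(str)
        if positive_label not in set(groups):
            raise ValueError(
                f"group level {positive_label!r} not present; levels are "
                f"{self.group_levels}"
            )
        return (groups == positive_label).to_numpy(dtype=int)

    @property
    def severity(self) -> pd.Series:
        if SEVERITY_COLUMN not in self.table.columns:
            raise ValueError(
                f"phenotype table has no {SEVERITY_COLUMN!r} column"
            )
        return self.table[SEVERITY_COLUMN]


def write_matrices(directory: str | Path,
                   matrices: list[ConnectivityMatrix] | list[np.ndarray],
                   subject_ids: list[str]) -> list[Path]:
    """Write one ``<subject_id>.txt`` matrix file per subject."""
    if len(matrices) != len(subject_ids):
        raise ValueError("one subject id per matrix required")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, mat in zip(subject_ids, matrices):
        values = mat.values if isinstance(mat, ConnectivityMatrix) else mat
        path = directory / f"{sid}.txt"
        np.savetxt(path, np.asarray(values, dtype=float), fmt="%.12g")
        paths.append(path)
    return paths


def read_matrices(path: str | Path,
                  roi_labels: tuple[str, ...] | list[str] = (),
                  ) -> tuple[list[ConnectivityMatrix], list[str]]:
    """Read all ``*.txt`` matrices from a directory (or a single file).

    Returns the matrices and the subject ids (file stems), sorted by id.
    Validation failures report the offending file; asymmetric matrices are
    rejected with the maximum asymmetry.
    """
    path = Path(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no .txt matrix files under {path}")
    matrices, ids = [], []
    for f in files:
        values = np.loadtxt(f, ndmin=2)
        asym = np.abs(values - values.T).max()
        if asym > 1e-8:
            raise ValueError(
                f"{f.name}: matrix is asymmetric (max |S - S^T| = {asym:.3e})"
            )
        try:
            matrices.append(ConnectivityMatrix(0.5 * (values + values.T),
                                               tuple(roi_labels)))
        except ValueError as exc:
            raise ValueError(f"{f.name}: {exc}") from exc
        ids.append(f.stem)
    return matrices, ids


def read_phenotypes(path: str | Path) -> CohortTable:
    """Read and validate a phenotype CSV."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{Path(path).name}: missing required column(s) {missing}"
        )
    return CohortTable(df)


def write_phenotypes(path: str | Path, cohort: CohortTable) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(path, index=False)
    return path
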