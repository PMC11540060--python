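"""Labeled matrix containers and CSV/TSV round-trip I/O.

All matrices carried through the pipeline are labeled: a similarity matrix
over one entity set (microbes or diseases), the binary association matrix
linking the two sets, and the dense score matrix the model emits.  Files are
plain CSV or TSV with a mandatory header row of column IDs and a mandatory
first column of row IDs, so that row order can never silently drift between
the similarity inputs and the association labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "AssociationMatrix",
    "ScoreMatrix",
    "read_matrix",
    "write_matrix",
    "write_scores",
    "MatrixValidationError",
]

SYMMETRY_TOL = 1e-8


class MatrixValidationError(ValueError):
    """A labeled matrix violated one of its structural invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixValidationError(f"duplicate {what} ID {i!r}")
        seen.add(i)


@dataclass
class SimilarityMatrix:
    """Square similarity matrix over one entity set.

    Raw input similarities are symmetric with entries in [0, 1]; fused
    feature matrices reuse this container but may hold any finite reals,
    so range/symmetry checks are opt-in via :meth:`validate_input`.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixValidationError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} IDs"
            )
        _check_unique(self.ids, "entity")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"non-finite similarity at ({self.ids[i]!r}, {self.ids[j]!r})"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate_input(self, tol: float = SYMMETRY_TOL) -> "SimilarityMatrix":
        """Enforce the raw-input contract: symmetric, entries in [0, 1]."""
        v = self.values
        bad = (v < 0) | (v > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"similarity {v[i, j]!r} outside [0, 1] at row "
                f"{self.ids[i]!r}, column {self.ids[j]!r}"
            )
        asym = np.abs(v - v.T)
        if asym.max(initial=0.0) > tol:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise MatrixValidationError(
                f"asymmetry {asym[i, j]:.3g} > {tol:g} between "
                f"{self.ids[i]!r} and {self.ids[j]!r}"
            )
        return self


@dataclass
class AssociationMatrix:
    """Binary microbe x disease association matrix (the gold labels)."""

    microbe_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.microbe_ids = [str(i) for i in self.microbe_ids]
        self.disease_ids = [str(i) for i in self.disease_ids]
        if self.values.shape != (len(self.microbe_ids), len(self.disease_ids)):
            raise MatrixValidationError(
                f"association shape {self.values.shape} does not match "
                f"{len(self.microbe_ids)} microbes x {len(self.disease_ids)} diseases"
            )
        _check_unique(self.microbe_ids, "microbe")
        _check_unique(self.disease_ids, "disease")
        nonbinary = ~np.isin(self.values, (0.0, 1.0))
        if nonbinary.any():
            i, j = np.argwhere(nonbinary)[0]
            raise MatrixValidationError(
                f"non-binary association value {self.values[i, j]!r} at "
                f"({self.microbe_ids[i]!r}, {self.disease_ids[j]!r})"
            )

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def positive_pairs(self) -> np.ndarray:
        """(n_pos, 2) array of (microbe index, disease index) for A == 1."""
        return np.argwhere(self.values == 1.0)


@dataclass
class ScoreMatrix:
    """Predicted association probabilities, strictly inside (0, 1)."""

    microbe_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_matrix(path: str | Path, expect_square: bool = False):
    """Read a labeled CSV/TSV matrix.

    With ``expect_square`` the file is returned as a
    :class:`SimilarityMatrix` validated symmetric with entries in [0, 1].
    Otherwise a binary table becomes an :class:`AssociationMatrix` and any
    other numeric table a :class:`ScoreMatrix`, so score files round-trip
    through the same reader.  Delimiter is chosen by extension:
    ``.tsv``/``.tab`` are tab-separated, anything else comma-separated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise MatrixValidationError(f"{path}: malformed table: {exc}") from exc
    if df.columns.duplicated().any() or df.index.duplicated().any():
        raise MatrixValidationError(f"{path}: duplicate row or column IDs")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MatrixValidationError(f"{path}: non-numeric cell: {exc}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise MatrixValidationError(
            f"{path}: missing/non-numeric cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if expect_square:
        if row_ids != col_ids:
            raise MatrixValidationError(
                f"{path}: square matrix expected but row IDs differ from "
                "column IDs"
            )
        return SimilarityMatrix(row_ids, values).validate_input()
    if np.isin(values, (0.0, 1.0)).all():
        return AssociationMatrix(row_ids, col_ids, values)
    return ScoreMatrix(row_ids, col_ids, values)


def _frame(values: np.ndarray, rows: Sequence[str], cols: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(values, index=list(rows), columns=list(cols))


def write_matrix(matrix, path: str | Path) -> None:
    """Write any labeled matrix container to CSV/TSV (lossless round-trip)."""
    path = Path(path)
    if isinstance(matrix, SimilarityMatrix):
        df = _frame(matrix.values, matrix.ids, matrix.ids)
    else:
        df = _frame(matrix.values, matrix.microbe_ids, matrix.disease_ids)
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Write a score matrix; scores must be finite and strictly in (0, 1)."""
    v = scores.values
    if not np.all(np.isfinite(v)):
        raise MatrixValidationError("score matrix contains non-finite values")
    if (v <= 0).any() or (v >= 1).any():
        raise MatrixValidationError("scores must lie strictly inside (0, 1)")
    write_matrix(scores, path)
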