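"""Expression tables: reading, writing, qPCR transforms and binarization.

Tables are delimited text (CSV/TSV), one row per cell, one column per gene,
plus an id column and a population-label column. Two published Ct-to-
expression conventions are supported: ``guo`` (expression = background Ct of
28 minus raw Ct, clamped at 0) and ``pina`` (expression = (30 - dCt) * ln 2,
with dCt at or past the detection limit of 30 meaning undetected).
Binarization is strict: a call is "on" iff expression > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "ExpressionMatrix",
    "BinaryMatrix",
    "read_expression_table",
    "write_expression_table",
    "transform_ct_guo",
    "transform_dct_pina",
    "binarize",
    "GUO_BACKGROUND_CT",
    "PINA_DETECTION_LIMIT",
    "TRANSFORMS",
]

GUO_BACKGROUND_CT = 28.0
PINA_DETECTION_LIMIT = 30.0

_DELIMITERS = {"csv": ",", "tsv": "\t"}


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise InputError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Cells x genes table of non-negative expression with population labels.

    A value of 0 means "no measurable gene expression"; anything positive is
    a detected transcript level.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    population: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.population = [str(p) for p in self.population]
        if self.values.ndim != 2:
            raise InputError("expression values must be a 2-D cells x genes array")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.population) != n:
            raise InputError("cell_ids and population must have one entry per row")
        if len(self.gene_ids) != g:
            raise InputError("gene_ids must have one entry per column")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"non-finite expression at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise InputError(
                f"negative expression at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self, label_column: str = "population") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)
        df.insert(0, label_column, self.population)
        df.index.name = "cell_id"
        return df


@dataclass
class BinaryMatrix:
    """On/off calls with the same shape and labels as the source matrix."""

    calls: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    population: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if not np.isin(self.calls, (0, 1)).all():
            raise InputError("calls must all be 0 or 1")
        self.calls = self.calls.astype(np.int8)
        if self.calls.ndim != 2:
            raise InputError("calls must be a 2-D cells x genes array")
        n, g = self.calls.shape
        if len(self.cell_ids) != n or len(self.population) != n:
            raise InputError("cell_ids and population must have one entry per row")
        if len(self.gene_ids) != g:
            raise InputError("gene_ids must have one entry per column")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")

    @property
    def n_cells(self) -> int:
        return self.calls.shape[0]

    @property
    def n_genes(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.population))

    def subset(self, population: str) -> np.ndarray:
        """Calls of the cells belonging to one population."""
        mask = np.asarray([p == population for p in self.population])
        if not mask.any():
            raise InputError(f"unknown population {population!r}")
        return self.calls[mask]


def transform_ct_guo(raw_ct, background: float = GUO_BACKGROUND_CT):
    """Raw Ct -> expression: ``max(0, background - raw_ct)``.

    Ct cycles count PCR doublings to detection, so background minus Ct is a
    log2 expression above the system background; values past the background
    are undetected and map to 0. Accepts scalars or arrays.
    """
    arr = np.asarray(raw_ct, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("raw Ct values must be finite")
    out = np.maximum(0.0, background - arr)
    return float(out) if out.ndim == 0 else out


def transform_dct_pina(delta_ct, limit: float = PINA_DETECTION_LIMIT):
    """dCt to a reference gene -> expression: ``(limit - dCt) * ln 2``.

    dCt at or beyond the detection limit means undetected and maps to 0.
    Accepts scalars or arrays.
    """
    arr = np.asarray(delta_ct, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("delta Ct values must be finite")
    out = np.where(arr < limit, (limit - arr) * np.log(2.0), 0.0)
    return float(out) if out.ndim == 0 else out


TRANSFORMS = {
    "none": None,
    "guo": transform_ct_guo,
    "pina": transform_dct_pina,
}


def read_expression_table(
    path,
    dialect: str = "csv",
    label_column: str = "population",
    transform: str = "none",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a delimited cells x genes table into an :class:`ExpressionMatrix`.

    The first column holds cell ids; ``label_column`` holds population
    labels. With ``transpose`` the file is genes x cells and is flipped after
    reading (the label column then still refers to cells and must be a row).
    ``transform`` applies one of the Ct conventions to every numeric value
    before validation, so raw Ct / dCt tables can be loaded directly.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if dialect not in _DELIMITERS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    if transform not in TRANSFORMS:
        raise ConfigurationError(
            f"unknown transform {transform!r}; use one of {sorted(TRANSFORMS)}"
        )
    df = pd.read_csv(path, sep=_DELIMITERS[dialect], index_col=0)
    if transpose:
        df = df.T
    if df.shape[1] < 2:
        raise InputError(
            f"{path}: parsed only {df.shape[1]} column(s); wrong dialect?"
        )
    if label_column not in df.columns:
        raise ConfigurationError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(df.columns)[:8]}...)"
        )
    labels = df[label_column].astype(str).tolist()
    expr = df.drop(columns=[label_column])
    for col in expr.columns:
        coerced = pd.to_numeric(expr[col], errors="coerce")
        bad = coerced.isna() & expr[col].notna()
        if bad.any():
            row = expr.index[bad.argmax()]
            raise InputError(
                f"{path}: non-numeric expression at row {row!r}, column {col!r}"
            )
        if coerced.isna().any():
            row = expr.index[coerced.isna().argmax()]
            raise InputError(f"{path}: missing value at row {row!r}, column {col!r}")
        expr[col] = coerced
    values = expr.to_numpy(dtype=float)
    fn = TRANSFORMS[transform]
    if fn is not None:
        values = fn(values)
    return ExpressionMatrix(
        values=values,
        cell_ids=[str(i) for i in expr.index],
        gene_ids=[str(c) for c in expr.columns],
        population=labels,
    )


def write_expression_table(
    m: ExpressionMatrix,
    path,
    dialect: str = "csv",
    label_column: str = "population",
) -> None:
    """Write an :class:`ExpressionMatrix` as delimited text (round-trippable)."""
    if dialect not in _DELIMITERS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = m.to_frame(label_column=label_column)
    df.to_csv(path, sep=_DELIMITERS[dialect], float_format="%.12g")


def binarize(m: ExpressionMatrix) -> BinaryMatrix:
    """Call a gene "on" in a cell iff its expression is strictly positive."""
    return BinaryMatrix(
        calls=(m.values > 0).astype(np.int8),
        cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids),
        population=list(m.population),
    )
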