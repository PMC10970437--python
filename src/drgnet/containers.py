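"""Core data containers shared across the package.

An :class:`ExpressionMatrix` holds a cell-lines-by-genes expression matrix
with unique row and column identifiers; a :class:`SensitivityProfile` holds
one continuous drug-sensitivity scalar per cell line.  Both are thin,
validated wrappers around a :class:`pandas.DataFrame` / :class:`pandas.Series`
so that the numerical code can work on plain ``numpy`` arrays while I/O and
alignment stay id-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "SensitivityProfile", "align"]


@dataclass
class ExpressionMatrix:
    """Cell lines x genes numeric expression matrix.

    Parameters
    ----------
    values
        ``(n, p)`` float array; rows are cell lines, columns genes.
    cell_line_ids
        ``n`` unique identifiers.
    gene_ids
        ``p`` unique identifiers.
    gene_meta
        Optional per-gene metadata (e.g. Entrez ids parsed from DepMap
        headers), keyed by gene id.
    """

    values: np.ndarray
    cell_line_ids: list[str]
    gene_ids: list[str]
    gene_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_line_ids = [str(c) for c in self.cell_line_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.cell_line_ids) != n:
            raise ValueError(f"{len(self.cell_line_ids)} cell-line ids for {n} rows")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(set(self.cell_line_ids)) != n:
            raise ValueError("cell-line ids must be unique")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_cell_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.cell_line_ids),
            [self.gene_ids[i] for i in idx],
            {g: self.gene_meta[g] for g in gene_ids if g in self.gene_meta},
        )

    def subset_cell_lines(self, cell_line_ids: list[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cell_line_ids)}
        idx = [pos[c] for c in cell_line_ids]
        return ExpressionMatrix(
            self.values[idx], list(cell_line_ids), list(self.gene_ids), dict(self.gene_meta)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_line_ids, columns=self.gene_ids)

    def to_csv(self, path) -> None:
        """Write in the DepMap dialect: first column = cell-line id."""
        frame = self.to_frame()
        frame.index.name = "cell_line"
        frame.to_csv(path)


@dataclass
class SensitivityProfile:
    """One continuous drug-sensitivity value per cell line."""

    values: np.ndarray
    cell_line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.cell_line_ids = [str(c) for c in self.cell_line_ids]
        if len(self.cell_line_ids) != self.values.size:
            raise ValueError("sensitivity values and ids differ in length")
        if len(set(self.cell_line_ids)) != len(self.cell_line_ids):
            raise ValueError("cell-line ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensitivity profile contains non-finite values")

    @property
    def n_cell_lines(self) -> int:
        return self.values.size

    def value_of(self, cell_line_id: str) -> float:
        try:
            i = self.cell_line_ids.index(cell_line_id)
        except ValueError:
            raise KeyError(f"unknown cell line: {cell_line_id!r}") from None
        return float(self.values[i])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.cell_line_ids, name="sensitivity")

    def to_csv(self, path) -> None:
        frame = self.to_series().rename_axis("cell_line").reset_index()
        frame.to_csv(path, index=False)


def align(
    expr: ExpressionMatrix, profile: SensitivityProfile
) -> tuple[ExpressionMatrix, SensitivityProfile, int]:
    """Restrict both inputs to their common cell lines (order of ``expr``).

    Returns the aligned pair and the number of cell lines dropped from the
    union of the two id sets.
    """
    common = [c for c in expr.cell_line_ids if c in set(profile.cell_line_ids)]
    if not common:
        raise ValueError("expression and sensitivity share no cell lines")
    dropped = len(set(expr.cell_line_ids) | set(profile.cell_line_ids)) - len(common)
    expr_a = expr.subset_cell_lines(common)
    prof_a = SensitivityProfile(
        np.array([profile.value_of(c) for c in common]), common
    )
    return expr_a, prof_a, dropped
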