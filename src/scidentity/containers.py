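"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`: a dense genes x columns
matrix of non-negative, log-scale expression values (bulk samples or single
cells in the columns).  Gene and column identifiers are ordered and unique;
per-column metadata carries condition and cluster labels for single-cell
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GeneSetCollection", "normalize_gene_id"]


def normalize_gene_id(gene: str) -> str:
    """Canonical form used when matching gene identifiers across datasets.

    Uppercases and strips a trailing numeric version suffix (``".7"`` in
    ``ENSG00000136997.7``) so that bulk and single-cell gene lists produced
    by different quantification pipelines can be intersected.
    """
    gene = gene.strip().upper()
    head, sep, tail = gene.rpartition(".")
    if sep and tail.isdigit():
        return head
    return gene


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate {what} identifier: {i!r}")
            seen.add(i)


@dataclass
class ExpressionMatrix:
    """Dense non-negative expression matrix, genes in rows.

    Parameters
    ----------
    values
        2-D float array of shape ``(n_genes, n_columns)``; no missing
        values, all entries >= 0 (log-scale expression or raw counts).
    gene_ids, column_ids
        Ordered unique identifiers for rows / columns.
    column_meta
        Optional ``column_id -> {"condition": ..., "cluster": ...}`` map;
        keys must be a subset of ``column_ids``.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    column_meta: dict[str, dict[str, str]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.column_ids = list(self.column_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if np.isnan(self.values).any():
            g, c = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[g]!r}, "
                f"column {self.column_ids[c]!r}"
            )
        if (self.values < 0).any():
            g, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[g]!r}, "
                f"column {self.column_ids[c]!r} (matrix must be "
                "log-transformed non-negative)"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.column_ids, "column")
        if self.column_meta is not None:
            unknown = set(self.column_meta) - set(self.column_ids)
            if unknown:
                raise ValueError(
                    f"column_meta keys not in column_ids: {sorted(unknown)[:5]}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def gene_index(self, gene: str) -> int:
        """Row index of ``gene``; falls back to normalized-id matching."""
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            norm = normalize_gene_id(gene)
            for i, g in enumerate(self.gene_ids):
                if normalize_gene_id(g) == norm:
                    return i
            raise KeyError(f"gene {gene!r} not found") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx],
            list(self.column_ids), self.column_meta,
        )

    def subset_columns(self, columns: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: j for j, c in enumerate(self.column_ids)}
        idx = [pos[c] for c in columns]
        meta = None
        if self.column_meta is not None:
            meta = {c: self.column_meta[c] for c in columns if c in self.column_meta}
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), list(columns), meta
        )

    def condition_of(self, column: str) -> str:
        if self.column_meta and column in self.column_meta:
            return self.column_meta[column].get("condition", "")
        return ""

    def cluster_of(self, column: str) -> str:
        if self.column_meta and column in self.column_meta:
            return self.column_meta[column].get("cluster", "")
        return ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB hallmarks read from GMT)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)
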