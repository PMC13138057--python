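"""Readers and writers for every external format the pipeline touches.

Formats: TSV/CSV expression tables, MatrixMarket triplet bundles
(matrix.mtx + features.tsv + barcodes.tsv), GMT gene sets, and a JSON
serialization of fitted identity models.  All writers are exact inverses of
their readers at double precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, GeneSetCollection

if TYPE_CHECKING:  # pragma: no cover
    from .nmf import IdentityModel

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_mtx_bundle", "write_mtx_bundle",
    "read_gmt", "write_gmt",
    "read_model", "write_model",
    "MODEL_SCHEMA_VERSION",
]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_tsv(
    path: str | Path, orientation: str = "genes_in_rows"
) -> ExpressionMatrix:
    """Read a dense expression table with a header row and an id column.

    ``orientation="genes_in_columns"`` transposes on read so that the
    returned matrix always has genes in rows.  Duplicate gene ids are
    collapsed by keeping the row with the highest mean expression (logged).
    """
    if orientation not in ("genes_in_rows", "genes_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "genes_in_columns":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if np.isnan(values).any():
        g, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at gene {df.index[g]!r}, column {df.columns[c]!r}"
        )
    if (values < 0).any():
        g, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value at gene {df.index[g]!r}, column {df.columns[c]!r} "
            "(matrix must be log-transformed non-negative)"
        )
    if df.index.has_duplicates:
        means = values.mean(axis=1)
        keep: dict[str, int] = {}
        for i, g in enumerate(df.index):
            if g not in keep or means[i] > means[keep[g]]:
                keep[g] = i
        dropped = len(df.index) - len(keep)
        logger.warning(
            "collapsed %d duplicate gene rows in %s (kept highest-mean row)",
            dropped, path,
        )
        order = sorted(keep.values())
        df = df.iloc[order]
        values = values[order]
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene")


def read_mtx_bundle(
    matrix: str | Path,
    features: str | Path,
    barcodes: str | Path,
    feature_column: int = 0,
) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate matrix plus feature/barcode lists.

    The matrix is materialized dense, genes x cells; implicit entries are
    zero.  ``feature_column`` selects the column of features.tsv used as the
    gene identifier (10x-style files put symbols in column 1).
    """
    mat = scipy.io.mmread(str(matrix))
    feats = [
        line.rstrip("\n").split("\t")[feature_column]
        for line in Path(features).read_text().splitlines()
        if line.strip()
    ]
    cells = [
        line.strip() for line in Path(barcodes).read_text().splitlines() if line.strip()
    ]
    if mat.shape != (len(feats), len(cells)):
        raise ValueError(
            f"dimension mismatch: matrix header says {mat.shape}, but "
            f"features.tsv has {len(feats)} and barcodes.tsv has {len(cells)} entries"
        )
    dense = np.asarray(
        mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    return ExpressionMatrix(dense, feats, cells)


def write_mtx_bundle(
    expr: ExpressionMatrix,
    matrix: str | Path,
    features: str | Path,
    barcodes: str | Path,
) -> None:
    sparse = scipy.sparse.coo_matrix(expr.values)
    scipy.io.mmwrite(str(matrix), sparse)
    Path(features).write_text("".join(g + "\n" for g in expr.gene_ids))
    Path(barcodes).write_text("".join(c + "\n" for c in expr.column_ids))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    The description field is discarded; duplicate genes within a set are
    deduplicated (order preserved); a duplicated set name is an error.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        name, _desc, *genes = fields
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = list(dict.fromkeys(g for g in genes if g))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# -- identity model serialization ---------------------------------------------


def write_model(model: "IdentityModel", path: str | Path) -> None:
    """Serialize a fitted identity model as one JSON document.

    Arrays are nested lists of Python floats, which JSON round-trips at full
    double precision; a schema version guards future format changes.
    """
    if len(model.gene_ids) == 0:
        raise ValueError("refusing to write a model with 0 genes")
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "k": int(model.k),
        "gene_ids": list(model.gene_ids),
        "sample_ids": list(model.sample_ids),
        "factor_names": list(model.factor_names),
        "W": model.W.tolist(),
        "H": model.H.tolist(),
        "recon_err_by_k": {str(k): float(v) for k, v in model.recon_err_by_k.items()},
        "sample_labels": dict(model.sample_labels),
        "gene_groups": dict(model.gene_groups),
        "H_zscores": model.H_zscores.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_model(path: str | Path) -> "IdentityModel":
    from .nmf import IdentityModel

    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version mismatch: file has {version!r}, "
            f"this package reads {MODEL_SCHEMA_VERSION}"
        )
    return IdentityModel(
        W=np.asarray(doc["W"], dtype=float),
        H=np.asarray(doc["H"], dtype=float),
        k=int(doc["k"]),
        gene_ids=list(doc["gene_ids"]),
        sample_ids=list(doc["sample_ids"]),
        factor_names=list(doc["factor_names"]),
        recon_err_by_k={int(k): float(v) for k, v in doc["recon_err_by_k"].items()},
        sample_labels=dict(doc["sample_labels"]),
        gene_groups=dict(doc["gene_groups"]),
        H_zscores=np.asarray(doc["H_zscores"], dtype=float),
    )
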