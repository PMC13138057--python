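"""Project single cells onto bulk-derived identity programs by NNLS.

Given the fixed gene-program matrix W from the bulk identity model, each
cell's expression vector x is decomposed as x ~ W h with h >= 0 (the
"reverse" factorization): h carries the per-identity weights of the cell,
the argmax factor becomes the assigned identity, and pooled z-scores of h
across all cells give comparable per-identity intensity scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import scipy.optimize

from .containers import ExpressionMatrix, normalize_gene_id
from .nmf import IdentityModel

logger = logging.getLogger(__name__)

__all__ = [
    "CellIdentityProfile",
    "normalize_cells",
    "harmonize_genes",
    "nnls_project",
    "map_cells",
    "profiles_to_frame",
]


@dataclass
class CellIdentityProfile:
    """Per-cell identity weights, assignment and pooled intensity scores."""

    cell_id: str
    h: np.ndarray                      # non-negative, length k
    assigned_identity: str
    identity_scores: np.ndarray        # z-scored h across all mapped cells
    condition: str = ""
    cluster: str = ""


def normalize_cells(raw_counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-10k + log1p normalization; all-zero cells are dropped.

    NNLS projection needs a non-negative log-scale representation on the
    same footing as the bulk log2(TPM+1) values; log1p(CP10k) is the
    standard depth-normalized choice.
    """
    if (raw_counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    totals = raw_counts.values.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = [c for c, k in zip(raw_counts.column_ids, keep) if not k]
        logger.warning("dropping %d all-zero cells: %s...", len(dropped), dropped[:5])
    values = raw_counts.values[:, keep]
    totals = totals[keep]
    cols = [c for c, k in zip(raw_counts.column_ids, keep) if k]
    cp10k = values / totals * 1e4
    meta = None
    if raw_counts.column_meta is not None:
        meta = {c: raw_counts.column_meta[c] for c in cols if c in raw_counts.column_meta}
    return ExpressionMatrix(np.log1p(cp10k), list(raw_counts.gene_ids), cols, meta)


class Harmonized(NamedTuple):
    W: np.ndarray                  # model genes x k, restricted
    sc: ExpressionMatrix           # same genes, same order
    genes: list[str]               # model gene ids retained
    fraction: float                # retained fraction of model genes


def harmonize_genes(
    model_genes: Sequence[str],
    W: np.ndarray,
    sc_expr: ExpressionMatrix,
) -> Harmonized:
    """Restrict W and the single-cell matrix to their shared genes.

    Identifiers are matched on the normalized form (uppercased, version
    suffix stripped).  An intersection below 50% of the model genes makes
    the projection unreliable and is an error; anything below 100% logs the
    retained fraction.
    """
    W = np.asarray(W, dtype=float)
    sc_map: dict[str, int] = {}
    for i, g in enumerate(sc_expr.gene_ids):
        sc_map.setdefault(normalize_gene_id(g), i)
    keep_model: list[int] = []
    keep_sc: list[int] = []
    genes: list[str] = []
    for i, g in enumerate(model_genes):
        j = sc_map.get(normalize_gene_id(g))
        if j is not None:
            keep_model.append(i)
            keep_sc.append(j)
            genes.append(g)
    fraction = len(genes) / len(model_genes) if len(model_genes) else 0.0
    if fraction < 0.5:
        raise ValueError(
            f"only {fraction:.0%} of model genes found in the single-cell "
            "matrix; projection would be unreliable"
        )
    if fraction < 1.0:
        logger.warning("gene harmonization retained %.1f%% of model genes",
                       100 * fraction)
    sc = ExpressionMatrix(
        sc_expr.values[keep_sc],
        [sc_expr.gene_ids[j] for j in keep_sc],
        list(sc_expr.column_ids),
        sc_expr.column_meta,
    )
    return Harmonized(W[keep_model], sc, genes, fraction)


def nnls_project(cell_vec: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve min ||x - W h||_2 subject to h >= 0 for one cell."""
    h, _ = scipy.optimize.nnls(np.asarray(W, float), np.asarray(cell_vec, float))
    return h


def map_cells(
    sc_expr: ExpressionMatrix,
    model: IdentityModel,
) -> list[CellIdentityProfile]:
    """Project every cell onto the model and assign identities.

    The assigned identity is the canonical name of the argmax weight (ties
    break to the lowest factor index, the behaviour of argmax); a cell with
    h = 0 is "unassigned".  identity_scores are per-factor z-scores of h
    pooled over all cells in the dataset so that conditions share one scale.
    """
    harm = harmonize_genes(model.gene_ids, model.W, sc_expr)
    n_cells = harm.sc.n_columns
    Hc = np.empty((n_cells, model.k))
    for j in range(n_cells):
        Hc[j] = nnls_project(harm.sc.values[:, j], harm.W)
    mean = Hc.mean(axis=0)
    sd = Hc.std(axis=0, ddof=0)
    scores = np.zeros_like(Hc)
    ok = sd > 0
    scores[:, ok] = (Hc[:, ok] - mean[ok]) / sd[ok]
    profiles: list[CellIdentityProfile] = []
    for j, cell in enumerate(harm.sc.column_ids):
        h = Hc[j]
        assigned = (
            model.factor_names[int(np.argmax(h))] if h.max() > 0 else "unassigned"
        )
        profiles.append(
            CellIdentityProfile(
                cell_id=cell,
                h=h,
                assigned_identity=assigned,
                identity_scores=scores[j],
                condition=harm.sc.condition_of(cell),
                cluster=harm.sc.cluster_of(cell),
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[CellIdentityProfile]):
    """Tabulate cell profiles (one row per cell) for TSV export."""
    import pandas as pd

    if not profiles:
        return pd.DataFrame()
    k = len(profiles[0].h)
    rows = []
    for p in profiles:
        row = {"cell_id": p.cell_id, "condition": p.condition, "cluster": p.cluster}
        row.update({f"h_F{i}": p.h[i] for i in range(k)})
        row.update({f"score_F{i}": p.identity_scores[i] for i in range(k)})
        row["assigned_identity"] = p.assigned_identity
        rows.append(row)
    return pd.DataFrame(rows)
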