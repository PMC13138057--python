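"""Quantify treatment-induced identity composition shifts.

Cell counts per identity are cross-tabulated against the control/treated
conditions; a chi-squared test of independence measures whether the
composition changed, and the Pearson residuals (O - E)/sqrt(E) of the
treated column give each identity a signed "residual score": positive means
the identity expanded under treatment, negative that it shrank.  The same
machinery, restricted to the most-expanded identity and cross-tabulating
cell clusters against conditions, apportions the expansion to clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .mapping import CellIdentityProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftResult",
    "identity_contingency",
    "chisq_residuals",
    "cluster_contributions",
]


@dataclass
class ShiftResult:
    """Contingency table, chi-squared statistic and residual scores."""

    table: pd.DataFrame            # rows x 2 conditions, integer counts
    chi2: float
    dof: int
    p_value: float
    residuals: pd.DataFrame        # same shape as table
    residual_scores: dict[str, float]   # treated-column residual per row
    most_expanded: str


def identity_contingency(
    profiles: Sequence[CellIdentityProfile],
    condition_pair: tuple[str, str],
) -> pd.DataFrame:
    """Identity x condition cell-count table for a (control, treated) pair.

    Unassigned cells are excluded (logged); identities absent from both
    conditions are dropped.  Column order is (control, treated).
    """
    control, treated = condition_pair
    counts: dict[str, dict[str, int]] = {}
    n_unassigned = 0
    for p in profiles:
        if p.condition not in (control, treated):
            continue
        if p.assigned_identity == "unassigned":
            n_unassigned += 1
            continue
        counts.setdefault(p.assigned_identity, {control: 0, treated: 0})
        counts[p.assigned_identity][p.condition] += 1
    if n_unassigned:
        logger.info("excluded %d unassigned cells", n_unassigned)
    if not counts:
        raise ValueError("no assigned cells in either condition")
    table = pd.DataFrame(counts).T.reindex(columns=[control, treated]).fillna(0)
    table = table.loc[sorted(table.index)].astype(int)
    table = table.loc[table.sum(axis=1) > 0]
    for cond in (control, treated):
        if table[cond].sum() == 0:
            raise ValueError(f"condition {cond!r} has 0 assigned cells")
    return table


def chisq_residuals(
    table: pd.DataFrame,
    correction: bool = False,
    residual_type: str = "pearson",
) -> ShiftResult:
    """Chi-squared test of independence with per-cell residual scores.

    Expected counts are E_ij = row_i * col_j / N; the statistic is
    sum (O-E)^2/E (optionally Yates-corrected for 2x2 tables), dof is
    (r-1)(c-1), and residuals are Pearson (O-E)/sqrt(E) by default or
    standardized (adjusted for margins) with ``residual_type="standardized"``.
    The residual score of a row is its residual in the treated (second)
    column; ``most_expanded`` is the row with the largest such score.
    """
    if residual_type not in ("pearson", "standardized"):
        raise ValueError(f"unknown residual_type {residual_type!r}")
    O = np.asarray(table, dtype=float)
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("table must have at least 2 rows and 2 columns")
    if (O < 0).any():
        raise ValueError("counts must be non-negative")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    N = O.sum()
    if (row == 0).any():
        bad = table.index[np.nonzero(row == 0)[0][0]]
        raise ValueError(f"row margin for {bad!r} is zero; expected counts vanish")
    if (col == 0).any():
        bad = table.columns[np.nonzero(col == 0)[0][0]]
        raise ValueError(f"column margin for {bad!r} is zero; expected counts vanish")
    E = np.outer(row, col) / N
    if correction and O.shape == (2, 2):
        stat = float((((np.abs(O - E) - 0.5).clip(min=0)) ** 2 / E).sum())
    else:
        stat = float(((O - E) ** 2 / E).sum())
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(chi2_dist.sf(stat, dof))
    resid = (O - E) / np.sqrt(E)
    if residual_type == "standardized":
        adj = np.sqrt(np.outer(1 - row / N, 1 - col / N))
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = np.where(adj > 0, resid / adj, 0.0)
    residuals = pd.DataFrame(resid, index=table.index, columns=table.columns)
    treated_col = table.columns[1]
    scores = residuals[treated_col].to_dict()
    most_expanded = max(scores, key=scores.get)
    return ShiftResult(
        table=table.copy(), chi2=stat, dof=dof, p_value=p,
        residuals=residuals, residual_scores=scores, most_expanded=most_expanded,
    )


def cluster_contributions(
    profiles: Sequence[CellIdentityProfile],
    expanded_identity: str,
    condition_pair: tuple[str, str],
    residual_type: str = "pearson",
) -> ShiftResult:
    """Apportion an identity's expansion to cell clusters.

    Restricted to cells assigned ``expanded_identity``, a cluster x
    condition count table is tested exactly as in :func:`chisq_residuals`;
    the treated-column residual of each cluster quantifies its positive or
    negative contribution to the expansion.
    """
    control, treated = condition_pair
    counts: dict[str, dict[str, int]] = {}
    for p in profiles:
        if p.assigned_identity != expanded_identity:
            continue
        if p.condition not in (control, treated):
            continue
        counts.setdefault(p.cluster, {control: 0, treated: 0})
        counts[p.cluster][p.condition] += 1
    table = pd.DataFrame(counts).T.reindex(columns=[control, treated]).fillna(0)
    table = table.loc[table.sum(axis=1) > 0].astype(int)
    if table.shape[0] < 2:
        raise ValueError(
            f"need >= 2 clusters with cells of identity {expanded_identity!r}"
        )
    table = table.loc[sorted(table.index)]
    return chisq_residuals(table, residual_type=residual_type)
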