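"""Salient-gene selection by anchor-paired DBSCAN clustering.

Each candidate gene is paired with a fixed anchor gene (MYC by default) and
the samples are viewed as 2-D points (gene expression, anchor expression) in
raw log-expression units.  DBSCAN is run over a dense grid of eps values; a
gene is "salient" when at least one eps produces a pair of clusters that are
large enough, far apart (centroid distance) and, in cell-line mode, cleanly
separated (single-linkage gap).  Two procedure variants are provided: a
one-round cell-line filter with expression prefilters, and a two-round
tumor filter where cluster sizes are counted on a designated basal-like
sample subset.

DBSCAN is computed in-package from its density-reachability definition on a
precomputed distance matrix: the same gene is re-clustered at ~112 eps
values, so reusing the distance matrix across the grid is what makes a
genome-wide scan affordable.  The implementation is validated against
sklearn's DBSCAN in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSelectionConfig",
    "SalientGeneSet",
    "prefilter_genes",
    "dbscan_pair",
    "evaluate_gene",
    "select_salient_genes",
]


@dataclass
class GeneSelectionConfig:
    """Thresholds for the anchor-paired DBSCAN gene selection.

    Defaults are the cell-line values: expression prefilters at 3 (max and
    range, strict "lower than" removal), cluster pairs with more than
    ``min_cluster_size`` samples per cluster, centroid distance above 3 and
    single-linkage separation above 1.  ``mode="tumor_two_round"`` switches
    to the two-round tumor procedure (round 1: pair distance > 4 with at
    least 10 basal samples per cluster; round 2 on basal samples only:
    distance > 4 with at least 8 per cluster) and skips the prefilters.
    """

    anchor_gene: str = "MYC"
    mode: str = "cell_line"                # or "tumor_two_round"
    eps_start: float = 0.1
    eps_stop: float = 1.21
    eps_step: float = 0.01
    min_samples: int = 3                   # DBSCAN core-point threshold
    min_max_expr: float = 3.0
    min_range: float = 3.0
    min_cluster_size: int = 3              # strict: clusters need > this many
    min_centroid_dist: float = 3.0
    min_separation: float | None = 1.0
    tumor_round1_min_cluster: int = 10     # non-strict (at least this many)
    tumor_round2_min_cluster: int = 8      # non-strict
    tumor_min_centroid_dist: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in ("cell_line", "tumor_two_round"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.eps_start < self.eps_stop and self.eps_step > 0):
            raise ValueError("eps grid requires start < stop and step > 0")

    @property
    def eps_grid(self) -> np.ndarray:
        n = int(round((self.eps_stop - self.eps_start) / self.eps_step)) + 1
        return np.round(self.eps_start + self.eps_step * np.arange(n), 10)


@dataclass
class SalientGeneSet:
    """Selected genes (anchor first) with the accepting DBSCAN evidence."""

    genes: list[str]
    anchor: str
    per_gene_evidence: dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def prefilter_genes(expr: ExpressionMatrix, cfg: GeneSelectionConfig) -> list[str]:
    """Drop low/flat genes before clustering (cell-line mode only).

    A gene survives iff max(expr) >= min_max_expr and range >= min_range;
    the removal rule is strict ("lower than"), so boundary values stay.
    """
    mx = expr.values.max(axis=1)
    rng = mx - expr.values.min(axis=1)
    keep = [
        g for g, m, r in zip(expr.gene_ids, mx, rng)
        if not (m < cfg.min_max_expr or r < cfg.min_range)
    ]
    anchor_idx = expr.gene_index(cfg.anchor_gene)
    anchor = expr.gene_ids[anchor_idx]
    if anchor not in keep:
        raise ValueError(
            f"anchor gene {anchor!r} does not survive the expression prefilter"
        )
    return keep


def _dbscan_from_dist(dist: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN labels (-1 = noise) from a precomputed distance matrix.

    A core point has >= min_samples points within eps (inclusive, counting
    itself); clusters are the density-connected components, grown in index
    order so labels are deterministic.
    """
    n = dist.shape[0]
    neighbors = dist <= eps
    core = neighbors.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for nb in np.nonzero(neighbors[j])[0]:
                if labels[nb] == -1:
                    labels[nb] = cid
                    if core[nb]:
                        stack.append(int(nb))
        cid += 1
    return labels


def dbscan_pair(
    gene_vec: np.ndarray,
    anchor_vec: np.ndarray,
    eps: float,
    min_samples: int,
) -> np.ndarray:
    """Cluster samples in the 2-D (gene, anchor) expression plane.

    Euclidean metric on the raw (unscaled) points; returns standard DBSCAN
    labels with -1 for noise.
    """
    gene_vec = np.asarray(gene_vec, dtype=float)
    anchor_vec = np.asarray(anchor_vec, dtype=float)
    if gene_vec.shape != anchor_vec.shape:
        raise ValueError("gene and anchor vectors must have the same length")
    pts = np.column_stack([gene_vec, anchor_vec])
    dist = squareform(pdist(pts))
    return _dbscan_from_dist(dist, eps, min_samples)


def _scan_eps_grid(
    pts: np.ndarray,
    eps_grid: np.ndarray,
    min_samples: int,
    min_cluster_size: int,
    size_strict: bool,
    min_centroid_dist: float,
    min_separation: float | None,
    count_mask: np.ndarray | None = None,
) -> dict | None:
    """Scan the eps grid for an accepting cluster pair; return best evidence.

    Cluster sizes are counted over ``count_mask`` samples when given (the
    tumor procedure counts basal-like samples only).  Among all accepting
    (eps, pair) combinations the one with the largest centroid distance is
    recorded as evidence.
    """
    dist = squareform(pdist(pts))
    best: dict | None = None
    for eps in eps_grid:
        labels = _dbscan_from_dist(dist, float(eps), min_samples)
        cluster_ids = np.unique(labels[labels >= 0])
        if len(cluster_ids) < 2:
            continue
        members = {c: np.nonzero(labels == c)[0] for c in cluster_ids}
        for a, b in combinations(cluster_ids, 2):
            ia, ib = members[a], members[b]
            if count_mask is None:
                na, nb = len(ia), len(ib)
            else:
                na = int(count_mask[ia].sum())
                nb = int(count_mask[ib].sum())
            if size_strict:
                if not (na > min_cluster_size and nb > min_cluster_size):
                    continue
            else:
                if not (na >= min_cluster_size and nb >= min_cluster_size):
                    continue
            centroid_dist = float(
                np.linalg.norm(pts[ia].mean(axis=0) - pts[ib].mean(axis=0))
            )
            if not centroid_dist > min_centroid_dist:
                continue
            separation = float(dist[np.ix_(ia, ib)].min())
            if min_separation is not None and not separation > min_separation:
                continue
            if best is None or centroid_dist > best["best_pair_centroid_dist"]:
                best = {
                    "best_eps": float(eps),
                    "best_pair_centroid_dist": centroid_dist,
                    "best_pair_min_sizes": (min(na, nb), max(na, nb)),
                    "separation": separation,
                }
    return best


def evaluate_gene(
    gene_vec: np.ndarray,
    anchor_vec: np.ndarray,
    cfg: GeneSelectionConfig,
) -> dict | None:
    """Cell-line acceptance test for one gene against the anchor.

    Returns the accepting evidence (eps, centroid distance, sizes,
    separation) or None when no (eps, cluster pair) passes all thresholds.
    """
    pts = np.column_stack(
        [np.asarray(gene_vec, float), np.asarray(anchor_vec, float)]
    )
    return _scan_eps_grid(
        pts,
        cfg.eps_grid,
        cfg.min_samples,
        cfg.min_cluster_size,
        size_strict=True,
        min_centroid_dist=cfg.min_centroid_dist,
        min_separation=cfg.min_separation,
    )


def select_salient_genes(
    expr: ExpressionMatrix,
    cfg: GeneSelectionConfig | None = None,
    basal_samples: Sequence[str] | None = None,
) -> SalientGeneSet:
    """Run the full gene-selection procedure and return the salient set.

    Cell-line mode: expression prefilter, then one DBSCAN round per gene
    with the strict size rule.  Tumor mode: round 1 over all samples with
    cluster sizes counted on ``basal_samples`` (non-strict, >= 10), then
    round 2 restricted to the basal samples (non-strict, >= 8); the anchor
    gene is always included without evaluation.  Output order is descending
    accepting centroid distance, then lexicographic, anchor first.
    """
    cfg = cfg or GeneSelectionConfig()
    anchor_idx = expr.gene_index(cfg.anchor_gene)
    anchor = expr.gene_ids[anchor_idx]

    if cfg.mode == "cell_line":
        candidates = prefilter_genes(expr, cfg)
        anchor_vec = expr.values[anchor_idx]
        evidence: dict[str, dict] = {}
        for g in candidates:
            if g == anchor:
                continue
            ev = evaluate_gene(expr.gene_values(g), anchor_vec, cfg)
            if ev is not None:
                evidence[g] = ev
    else:
        if basal_samples is None:
            raise ValueError("tumor_two_round mode requires basal_samples")
        basal = set(basal_samples)
        missing = basal - set(expr.column_ids)
        if missing:
            raise ValueError(f"basal samples not in matrix: {sorted(missing)[:5]}")
        mask = np.array([c in basal for c in expr.column_ids])
        anchor_vec = expr.values[anchor_idx]
        round1: list[str] = []
        for g in expr.gene_ids:
            if g == anchor:
                continue
            pts = np.column_stack([expr.gene_values(g), anchor_vec])
            ev = _scan_eps_grid(
                pts, cfg.eps_grid, cfg.min_samples,
                cfg.tumor_round1_min_cluster, size_strict=False,
                min_centroid_dist=cfg.tumor_min_centroid_dist,
                min_separation=None, count_mask=mask,
            )
            if ev is not None:
                round1.append(g)
        logger.info("tumor round 1 retained %d genes", len(round1))
        basal_cols = [c for c in expr.column_ids if c in basal]
        sub = expr.subset_columns(basal_cols)
        anchor_vec2 = sub.values[sub.gene_index(anchor)]
        evidence = {}
        for g in round1:
            pts = np.column_stack([sub.gene_values(g), anchor_vec2])
            ev = _scan_eps_grid(
                pts, cfg.eps_grid, cfg.min_samples,
                cfg.tumor_round2_min_cluster, size_strict=False,
                min_centroid_dist=cfg.tumor_min_centroid_dist,
                min_separation=None,
            )
            if ev is not None:
                evidence[g] = ev

    if not evidence:
        raise ValueError(
            "no gene passed the selection thresholds (the anchor alone is "
            "not a valid salient set); review min_cluster_size, "
            "min_centroid_dist and min_separation"
        )
    ordered = sorted(
        evidence, key=lambda g: (-evidence[g]["best_pair_centroid_dist"], g)
    )
    return SalientGeneSet(
        genes=[anchor] + ordered, anchor=anchor, per_gene_evidence=evidence
    )
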