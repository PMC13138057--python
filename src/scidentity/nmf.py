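"""Identity discovery: NMF on the salient-gene matrix, elbow rank selection,
and hierarchical-clustering-derived sample/gene identity groups.

The model is X ~ W H with X the non-negative salient-gene expression matrix
(genes x samples), W the gene programs ("identities", unit-L2 columns) and H
the per-sample program weights.  The rank k is chosen by the point of
maximum discrete curvature of the reconstruction-error curve ("elbow"), and
Ward hierarchical clustering of the normalized H columns groups samples into
transcriptionally distinct identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import NMF

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IdentityModel",
    "run_nmf",
    "choose_k_elbow",
    "assign_sample_identities",
    "group_genes_by_identity",
    "compute_H_zscores",
    "fit_identity_model",
]


@dataclass
class IdentityModel:
    """A fitted identity model: factors, rank, labels and gene groups."""

    W: np.ndarray                      # genes x k, unit-L2 columns
    H: np.ndarray                      # k x samples
    k: int
    gene_ids: list[str]
    sample_ids: list[str]
    factor_names: list[str]            # canonical "F0".."F(k-1)"
    recon_err_by_k: dict[int, float] = field(default_factory=dict)
    sample_labels: dict[str, str] = field(default_factory=dict)
    gene_groups: dict[str, str] = field(default_factory=dict)
    H_zscores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.shape[1] != self.k or self.H.shape[0] != self.k:
            raise ValueError("W/H inner dimension must equal k")
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("W and H must be non-negative")


def run_nmf(
    expr: ExpressionMatrix | np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts Frobenius NMF; W columns scaled to unit L2 norm.

    Restart i uses random initialization with seed ``seed + i``; the
    factorization with the smallest Frobenius reconstruction error wins, so
    the result is a deterministic function of (data, k, n_restarts, seed).
    """
    X = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be below min(matrix dims)={min(X.shape)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    for i in range(n_restarts):
        nmf = NMF(
            n_components=k,
            init="random",
            random_state=int(seed + i) % (2**31),
            max_iter=max_iter,
            tol=tol,
            beta_loss="frobenius",
            solver="cd",
        )
        with warnings.catch_warnings():
            # best-of-restarts at a tight tolerance: hitting max_iter is expected
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = nmf.fit_transform(X)
        H = nmf.components_
        err = float(np.linalg.norm(X - W @ H))
        if best is None or err < best[0]:
            best = (err, W, H)
    err, W, H = best
    norms = np.linalg.norm(W, axis=0)
    nz = norms > 0
    W = W.copy()
    H = H.copy()
    W[:, nz] /= norms[nz]
    H[nz] *= norms[nz, None]
    return W, H, err


def choose_k_elbow(recon_err_by_k: Mapping[int, float]) -> int:
    """Select the NMF rank at the elbow of the reconstruction-error curve.

    With drops ``d_k = err(k-1) - err(k)``, the elbow is the interior grid
    point maximizing the discrete curvature ``d_k - d_{k+1}``; ties resolve
    to the smallest k.  A monotone-increasing error curve is degenerate and
    returns the first grid point with a warning.
    """
    ks = sorted(recon_err_by_k)
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least 3 grid points")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"k grid must be contiguous, got {ks}")
    err = [float(recon_err_by_k[k]) for k in ks]
    if all(b > a for a, b in zip(err, err[1:])):
        logger.warning(
            "reconstruction error increases monotonically with k; "
            "returning the first grid point %d", ks[0],
        )
        return ks[0]
    best_k, best_curv = None, -np.inf
    for i in range(1, len(ks) - 1):
        d_k = err[i - 1] - err[i]
        d_next = err[i] - err[i + 1]
        curv = d_k - d_next
        if curv > best_curv:  # strict: ties keep the smallest k
            best_k, best_curv = ks[i], curv
    return best_k


def assign_sample_identities(
    H: np.ndarray,
    sample_ids: Sequence[str],
    factor_names: Sequence[str] | None = None,
    mixture_margin: float = 0.10,
) -> dict[str, str]:
    """Label samples by Ward clustering of the column-normalized H matrix.

    H columns are normalized to sum 1, clustered (Ward linkage, Euclidean)
    and cut into k clusters.  Each cluster is named after the factor with
    the highest mean normalized weight among its samples; when the top two
    factor means differ by less than ``mixture_margin`` (relative to the
    top), the cluster is labeled ``mixture:Fi+Fj``.  All-zero samples get
    "unassigned".
    """
    H = np.asarray(H, dtype=float)
    k, n = H.shape
    if factor_names is None:
        factor_names = [f"F{i}" for i in range(k)]
    totals = H.sum(axis=0)
    labels: dict[str, str] = {}
    valid = np.nonzero(totals > 0)[0]
    for j in np.nonzero(totals == 0)[0]:
        logger.warning("sample %s has an all-zero H column; unassigned", sample_ids[j])
        labels[sample_ids[j]] = "unassigned"
    if len(valid) == 0:
        return labels
    Hn = H[:, valid] / totals[valid]
    if len(valid) == 1:
        cluster_ids = np.array([1])
    else:
        Z = linkage(Hn.T, method="ward")
        cluster_ids = fcluster(Z, t=min(k, len(valid)), criterion="maxclust")
    for cid in np.unique(cluster_ids):
        members = valid[cluster_ids == cid]
        means = Hn[:, cluster_ids == cid].mean(axis=1)
        order = np.argsort(-means, kind="stable")
        top, second = order[0], order[1] if k > 1 else order[0]
        if k > 1 and means[top] > 0 and (
            (means[top] - means[second]) < mixture_margin * means[top]
        ):
            i, j = sorted((int(top), int(second)))
            name = f"mixture:{factor_names[i]}+{factor_names[j]}"
        else:
            name = factor_names[int(top)]
        for m in members:
            labels[sample_ids[m]] = name
    return labels


def group_genes_by_identity(
    W: np.ndarray,
    gene_ids: Sequence[str],
    factor_names: Sequence[str] | None = None,
) -> dict[str, str]:
    """Assign each salient gene to the factor with its largest W weight.

    Ties go to the lowest factor index; all-zero rows are "unassigned".
    """
    W = np.asarray(W, dtype=float)
    if factor_names is None:
        factor_names = [f"F{i}" for i in range(W.shape[1])]
    groups: dict[str, str] = {}
    for g, row in zip(gene_ids, W):
        if not row.any():
            groups[g] = "unassigned"
        else:
            groups[g] = factor_names[int(np.argmax(row))]
    return groups


def compute_H_zscores(H: np.ndarray) -> np.ndarray:
    """Per-factor z-scores of sample weights (population sd, ddof=0).

    A constant factor row has no spread and becomes a row of zeros.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[1] < 2:
        raise ValueError("H must be k x samples with >= 2 samples")
    mean = H.mean(axis=1, keepdims=True)
    sd = H.std(axis=1, ddof=0, keepdims=True)
    z = np.zeros_like(H)
    ok = sd[:, 0] > 0
    if not ok.all():
        logger.warning("constant H row(s) %s: z-scores set to 0", np.nonzero(~ok)[0])
    z[ok] = (H[ok] - mean[ok]) / sd[ok]
    return z


def fit_identity_model(
    expr: ExpressionMatrix,
    k_grid: Iterable[int] = range(4, 10),
    n_restarts: int = 10,
    seed: int = 0,
    mixture_margin: float = 0.10,
    k: int | None = None,
) -> IdentityModel:
    """Fit NMF over a rank grid, pick k by the elbow rule, and derive labels.

    Factors are canonicalized by descending total W-column mass (ties by
    index) and named F0..F(k-1), so labels do not depend on the arbitrary
    factor order returned by the solver.  Passing ``k`` skips rank
    selection.
    """
    fits: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    if k is None:
        for kk in sorted(set(int(v) for v in k_grid)):
            fits[kk] = run_nmf(expr, kk, n_restarts=n_restarts, seed=seed)
        recon = {kk: f[2] for kk, f in fits.items()}
        k = choose_k_elbow(recon)
        W, H, _ = fits[k]
    else:
        W, H, err = run_nmf(expr, int(k), n_restarts=n_restarts, seed=seed)
        recon = {int(k): err}
    order = np.argsort(-W.sum(axis=0), kind="stable")
    W = W[:, order]
    H = H[order]
    factor_names = [f"F{i}" for i in range(k)]
    model = IdentityModel(
        W=W, H=H, k=int(k),
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.column_ids),
        factor_names=factor_names,
        recon_err_by_k=recon,
    )
    model.sample_labels = assign_sample_identities(
        H, expr.column_ids, factor_names, mixture_margin=mixture_margin
    )
    model.gene_groups = group_genes_by_identity(W, expr.gene_ids, factor_names)
    model.H_zscores = compute_H_zscores(H)
    return model
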