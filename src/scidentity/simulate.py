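"""Synthetic data with planted ground truth for every pipeline stage.

The generator realizes the statistical structure the analysis assumes: bulk
samples are non-negative mixtures of k latent gene programs (disjoint
marker-gene blocks plus an overlap fraction) with sample-specific weights
and Gaussian noise; single cells are Dirichlet-perturbed, Poisson-sampled
draws around one program with condition-dependent composition; one drug's
AUC is linearly coupled to a program weight; and a multiome fixture plants
a per-condition linear relationship between one TF's motif accessibility
and its target gene set.  Every output is a deterministic function of a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .mapping import normalize_cells

__all__ = [
    "SyntheticTruth",
    "TFMultiomeData",
    "generate_bulk",
    "generate_single_cells",
    "generate_drug_table",
    "generate_tf_multiome",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one named sub-stream per operation so stages are independently reproducible
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class SyntheticTruth:
    """Planted parameters behind a synthetic dataset."""

    k_true: int
    W_true: np.ndarray                    # genes x k_true
    sample_weights: np.ndarray            # k_true x n_samples
    gene_ids: list[str]
    sample_ids: list[str]
    anchor_gene: str
    marker_blocks: dict[str, list[str]]   # identity name -> marker genes
    condition_compositions: dict[str, np.ndarray]
    drug_effect: dict
    tf_effect: dict
    seed: int
    cell_identity_labels: list[int] | None = None

    @property
    def identity_names(self) -> list[str]:
        return [f"F{i}" for i in range(self.k_true)]

    def __post_init__(self) -> None:
        for cond, comp in self.condition_compositions.items():
            comp = np.asarray(comp, dtype=float)
            if abs(comp.sum() - 1.0) > 1e-9:
                raise ValueError(f"composition for {cond!r} does not sum to 1")
            self.condition_compositions[cond] = comp
        if (np.linalg.norm(self.W_true, axis=0) == 0).any():
            raise ValueError("W_true has an all-zero column")


def generate_bulk(
    n_genes: int = 400,
    n_samples: int = 40,
    k_true: int = 4,
    program_overlap: float = 0.1,
    noise_sd: float = 0.3,
    seed: int = 0,
    shift_delta: float = 0.15,
    shift_identity: int = 0,
    anchor_gene: str = "MYC",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Bulk expression from k latent programs with planted marker blocks.

    Each program owns a disjoint block of marker genes with high weights
    (4-8 log units) plus ``program_overlap`` of the block shared with the
    next program; remaining genes are flat low-expression noise that the
    selection prefilters should remove.  The anchor gene sits in the first
    block, so its expression is bimodal across samples and anchor-paired
    clustering has signal.  Condition compositions for the downstream
    single-cell stages are uniform in "control" and shifted by
    ``shift_delta`` toward identity ``F{shift_identity}`` in "treated".
    """
    if k_true < 2:
        raise ValueError("k_true must be >= 2")
    if n_genes < 10 * k_true:
        raise ValueError("need n_genes >= 10 * k_true")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, 1)
    markers_per = max(8, n_genes // (2 * k_true))
    gene_ids = [anchor_gene] + [f"G{i:04d}" for i in range(1, n_genes)]

    W = rng.uniform(0.0, 0.2, size=(n_genes, k_true))
    blocks: list[list[int]] = []
    pos = 0
    for f in range(k_true):
        block = list(range(pos, pos + markers_per))
        pos += markers_per
        blocks.append(block)
        W[block, f] = rng.uniform(4.0, 8.0, size=len(block))
    # shared marker genes: the first overlap-fraction of each block also
    # loads on the next program
    n_shared = int(round(program_overlap * markers_per))
    for f in range(k_true):
        shared = blocks[f][:n_shared]
        W[shared, (f + 1) % k_true] = rng.uniform(2.0, 4.0, size=len(shared))
    # non-marker genes stay flat/low
    noise_rows = list(range(pos, n_genes))
    W[noise_rows] = rng.uniform(0.0, 0.5, size=(len(noise_rows), k_true))

    weights = rng.uniform(0.0, 0.08, size=(k_true, n_samples))
    primary = np.arange(n_samples) % k_true
    weights[primary, np.arange(n_samples)] = rng.uniform(0.8, 1.0, size=n_samples)

    # canonical identity order: descending total marker-block weight
    block_mass = np.array([W[blocks[f], f].sum() for f in range(k_true)])
    order = np.argsort(-block_mass, kind="stable")
    W = W[:, order]
    weights = weights[order]
    blocks = [blocks[f] for f in order]
    marker_blocks = {
        f"F{i}": [gene_ids[g] for g in blocks[i]] for i in range(k_true)
    }

    values = W @ weights
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    expr = ExpressionMatrix(values, gene_ids, sample_ids)

    control = np.full(k_true, 1.0 / k_true)
    treated = control.copy()
    treated[shift_identity] += shift_delta
    others = [i for i in range(k_true) if i != shift_identity]
    treated[others] -= shift_delta / len(others)
    if (treated < 0).any():
        raise ValueError("shift_delta too large for a uniform base composition")

    truth = SyntheticTruth(
        k_true=k_true,
        W_true=W,
        sample_weights=weights,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        anchor_gene=anchor_gene,
        marker_blocks=marker_blocks,
        condition_compositions={"control": control, "treated": treated},
        drug_effect={
            "drug": "DRUG000",
            "factor_index": int(shift_identity),
            "slope": -0.1,
            "noise_sd": 0.04,
            "intercept": 0.55,
        },
        tf_effect={
            "control": {"slope": 0.0, "noise_sd": 1.0, "access_mean": 0.0},
            "treated": {"slope": 1.0, "noise_sd": 1.0, "access_mean": 1.0},
        },
        seed=int(seed),
    )
    return expr, truth


def generate_single_cells(
    truth: SyntheticTruth,
    n_cells_per_condition: Mapping[str, int] | None = None,
    mixture_alpha: float = 50.0,
    depth: int = 2000,
    seed: int = 0,
    normalize: bool = True,
) -> tuple[ExpressionMatrix, list[str]]:
    """Single cells as noisy draws around one program per cell.

    Each cell samples its identity from its condition's composition; the
    expression profile is a Dirichlet perturbation (concentration
    ``mixture_alpha`` times the normalized program) of the identity's
    W_true column, scaled to ``depth`` and Poisson-sampled.  By default the
    counts are log1p(CP10k)-normalized; ``normalize=False`` returns raw
    counts (for MTX export).  The planted identity name doubles as the
    cell's cluster label.  Returns (matrix, planted identity names).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if n_cells_per_condition is None:
        n_cells_per_condition = {"control": 500, "treated": 500}
    unknown = set(n_cells_per_condition) - set(truth.condition_compositions)
    if unknown:
        raise ValueError(f"conditions without a composition: {sorted(unknown)}")
    rng = _rng(seed, 2)
    k = truth.k_true
    programs = truth.W_true / truth.W_true.sum(axis=0, keepdims=True)
    cols: list[np.ndarray] = []
    cell_ids: list[str] = []
    labels: list[str] = []
    meta: dict[str, dict[str, str]] = {}
    for cond in n_cells_per_condition:
        comp = truth.condition_compositions[cond]
        n = int(n_cells_per_condition[cond])
        idents = rng.choice(k, size=n, p=comp)
        for j, f in enumerate(idents):
            alpha = mixture_alpha * programs[:, f]
            gamma = rng.gamma(np.clip(alpha, 1e-12, None))
            p = gamma / gamma.sum() if gamma.sum() > 0 else programs[:, f]
            counts = rng.poisson(depth * p)
            cols.append(counts)
            cell = f"{cond}_{j:05d}"
            cell_ids.append(cell)
            name = truth.identity_names[int(f)]
            labels.append(name)
            meta[cell] = {"condition": cond, "cluster": name}
    matrix = ExpressionMatrix(
        np.column_stack(cols).astype(float), list(truth.gene_ids), cell_ids, meta
    )
    truth.cell_identity_labels = [int(truth.identity_names.index(l)) for l in labels]
    if normalize:
        matrix = normalize_cells(matrix)
    return matrix, labels


def generate_drug_table(
    truth: SyntheticTruth,
    n_drugs: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Drug x sample AUC table with one program-coupled drug.

    The designated drug's AUC is intercept + slope * z(program weight) +
    Gaussian noise (lower AUC = greater sensitivity, hence the negative
    default slope); every other drug is pure noise around a typical AUC.
    """
    if not truth.drug_effect:
        raise ValueError("truth has no drug_effect")
    rng = _rng(seed, 3)
    eff = truth.drug_effect
    w = truth.sample_weights[eff["factor_index"]]
    sd = w.std(ddof=0)
    z = (w - w.mean()) / sd if sd > 0 else np.zeros_like(w)
    rows = {}
    noise = rng.normal(0.0, eff["noise_sd"], size=len(z)) if eff["noise_sd"] > 0 else 0.0
    rows[eff["drug"]] = eff["intercept"] + eff["slope"] * z + noise
    for d in range(1, n_drugs):
        rows[f"DRUG{d:03d}"] = rng.normal(0.55, 0.08, size=len(z))
    return pd.DataFrame(rows, index=truth.sample_ids).T


@dataclass
class TFMultiomeData:
    """Paired accessibility/expression fixture with one planted TF."""

    accessibility: pd.DataFrame            # TF x cells
    expr: ExpressionMatrix                 # target + background genes x cells
    targets: dict[str, list[str]]          # TF -> target gene list
    pathway_genes: list[str]
    planted_tf: str
    conditions: dict[str, str] = field(default_factory=dict)  # cell -> condition


def generate_tf_multiome(
    truth: SyntheticTruth,
    n_cells: Mapping[str, int] | None = None,
    seed: int = 0,
    n_decoys: int = 20,
    n_targets: int = 30,
    n_background: int = 300,
) -> TFMultiomeData:
    """Per-cell motif accessibility paired with target-gene expression.

    The planted TF's accessibility is Normal(condition mean, 1); every
    target gene of the planted TF gains slope_condition * accessibility
    plus a shared per-cell noise term (sd = the condition's noise_sd), so
    the target-set score regressed on accessibility realizes
    R^2 = slope^2 var(a) / (slope^2 var(a) + noise_sd^2).  Decoy TFs get
    independent accessibility and uncoupled targets.
    """
    if n_cells is None:
        n_cells = {"control": 5000, "treated": 5000}
    missing = set(n_cells) - set(truth.tf_effect)
    if missing:
        raise ValueError(f"conditions missing from tf_effect: {sorted(missing)}")
    rng = _rng(seed, 4)
    tfs = [f"TF{i:02d}" for i in range(n_decoys + 1)]
    planted = tfs[0]
    targets = {
        tf: [f"{tf}_T{j:02d}" for j in range(n_targets)] for tf in tfs
    }
    background = [f"BG{j:04d}" for j in range(n_background)]
    gene_ids = [g for tf in tfs for g in targets[tf]] + background

    cell_ids: list[str] = []
    conds: list[str] = []
    for cond, n in n_cells.items():
        cell_ids += [f"{cond}_{j:05d}" for j in range(int(n))]
        conds += [cond] * int(n)
    n_total = len(cell_ids)

    access = np.empty((len(tfs), n_total))
    cond_arr = np.array(conds)
    for cond in n_cells:
        mask = cond_arr == cond
        eff = truth.tf_effect[cond]
        access[0, mask] = rng.normal(eff.get("access_mean", 0.0), 1.0, mask.sum())
    access[1:] = rng.normal(0.0, 1.0, size=(len(tfs) - 1, n_total))

    mu = rng.uniform(2.0, 6.0, size=len(gene_ids))
    expr = mu[:, None] + rng.normal(0.0, 0.1, size=(len(gene_ids), n_total))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    # planted coupling: shared cell noise + slope * accessibility on targets
    signal = np.zeros(n_total)
    for cond in n_cells:
        mask = cond_arr == cond
        eff = truth.tf_effect[cond]
        noise = rng.normal(0.0, eff["noise_sd"], mask.sum()) if eff["noise_sd"] > 0 else 0.0
        signal[mask] = eff["slope"] * access[0, mask] + noise
    planted_rows = [gene_pos[g] for g in targets[planted]]
    expr[planted_rows] += signal
    # decoys: shared per-cell noise uncorrelated with any accessibility
    for t, tf in enumerate(tfs[1:], start=1):
        decoy_noise = rng.normal(0.0, 1.0, n_total)
        expr[[gene_pos[g] for g in targets[tf]]] += decoy_noise
    expr = np.clip(expr, 0.0, None)

    meta = {c: {"condition": cond, "cluster": ""} for c, cond in zip(cell_ids, conds)}
    matrix = ExpressionMatrix(expr, gene_ids, cell_ids, meta)
    pathway = targets[planted][: n_targets // 2] + background[:10]
    return TFMultiomeData(
        accessibility=pd.DataFrame(access, index=tfs, columns=cell_ids),
        expr=matrix,
        targets=targets,
        pathway_genes=pathway,
        planted_tf=planted,
        conditions=dict(zip(cell_ids, conds)),
    )
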