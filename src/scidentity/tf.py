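"""Link TF motif accessibility to target gene-set expression.

Per-cell gene-set module scores (set mean minus an expression-bin-matched
control mean), per-condition ordinary-least-squares R-squared between a
TF's motif accessibility and its target-set score, the change in R-squared
after treatment (delta R^2), and a per-TF relevance table combining mean
accessibility shift, rank-sum significance of target upregulation (broad
and pathway-restricted), and the R^2 columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, mannwhitneyu

from .associations import adjust_bh
from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TFLinkageResult",
    "module_score",
    "tf_target_r2",
    "delta_r2",
    "tf_relevance_table",
    "linkage_to_frame",
]


@dataclass
class TFLinkageResult:
    """Per-TF linkage evidence across conditions."""

    tf: str
    accessibility_diff: float           # mean treated - mean control
    broad_p: float                      # one-sided target upregulation, all targets
    pathway_p: float                    # same, targets restricted to the pathway
    r2_by_condition: dict[str, float] = field(default_factory=dict)
    delta_r2: dict[str, float] = field(default_factory=dict)
    broad_p_adj: float = float("nan")
    pathway_p_adj: float = float("nan")


def module_score(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_genes: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-cell gene-set expression score with bin-matched controls.

    All genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-size bins; for every set gene, ``n_ctrl`` control genes
    are sampled (seeded) from its bin; the score of a cell is the mean over
    set genes minus the mean over the sampled control pool.  Passing
    ``control_genes`` overrides the sampled pool (the self-control
    configuration ``control_genes=gene_set`` gives an identically-zero
    score).  Set genes absent from the matrix are dropped with a log entry.
    """
    present = [g for g in gene_set if g in set(expr.gene_ids)]
    dropped = len(list(gene_set)) - len(present)
    if dropped:
        logger.info("module_score: dropped %d absent genes", dropped)
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    set_idx = [gene_pos[g] for g in present]
    set_mean = expr.values[set_idx].mean(axis=0)
    if control_genes is not None:
        ctrl_idx = [gene_pos[g] for g in control_genes if g in gene_pos]
        if not ctrl_idx:
            raise ValueError("no control gene present in the matrix")
        return set_mean - expr.values[ctrl_idx].mean(axis=0)
    rng = np.random.default_rng(int(seed))
    avg = expr.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_of = np.empty(expr.n_genes, dtype=int)
    for b, idx in enumerate(bins):
        bin_of[idx] = b
    in_set = np.zeros(expr.n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl_pool: list[int] = []
    for i in set_idx:
        members = bins[bin_of[i]]
        members = members[~in_set[members]]  # never control against the set itself
        if len(members) == 0:
            continue
        replace = len(members) < n_ctrl
        ctrl_pool.extend(rng.choice(members, size=n_ctrl, replace=replace))
    if not ctrl_pool:
        raise ValueError("control bins contain no genes outside the set")
    ctrl_mean = expr.values[ctrl_pool].mean(axis=0)
    return set_mean - ctrl_mean


def tf_target_r2(
    accessibility: np.ndarray,
    target_scores: np.ndarray,
    condition_mask: np.ndarray | None = None,
) -> float:
    """OLS R^2 of the target-set score on motif accessibility.

    Restricted to ``condition_mask`` cells when given (>= 3 required);
    zero-variance accessibility (or score) is flagged as NaN.
    """
    a = np.asarray(accessibility, dtype=float)
    s = np.asarray(target_scores, dtype=float)
    if condition_mask is not None:
        mask = np.asarray(condition_mask, dtype=bool)
        a, s = a[mask], s[mask]
    if len(a) < 3:
        raise ValueError("need >= 3 cells in the condition")
    if a.std(ddof=0) == 0 or s.std(ddof=0) == 0:
        logger.warning("zero-variance input; R^2 undefined")
        return float("nan")
    fit = linregress(a, s)
    return float(fit.rvalue**2)


def delta_r2(
    r2_by_condition: Mapping[str, float],
    control: str,
) -> dict[str, float]:
    """R^2 change of each treatment relative to the control condition."""
    if control not in r2_by_condition:
        raise ValueError(f"control condition {control!r} missing")
    base = r2_by_condition[control]
    return {
        cond: float(r2 - base)
        for cond, r2 in r2_by_condition.items()
        if cond != control
    }


def tf_relevance_table(
    accessibility: pd.DataFrame,
    expr: ExpressionMatrix,
    targets: Mapping[str, Sequence[str]],
    pathway_set: Sequence[str],
    control: str,
    treatments: Sequence[str] | str,
    focus_treatment: str | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> list[TFLinkageResult]:
    """Rank TFs by evidence that they drive treatment-induced upregulation.

    For every TF: the mean motif-accessibility difference between the focus
    treatment and control; a one-sided (greater) rank-sum p for the target
    module score in the focus treatment versus control, over all targets
    (broad) and over targets intersected with ``pathway_set`` (pathway;
    NaN when the intersection is empty); per-condition R^2 between
    accessibility and target score; and delta R^2 per treatment.  Broad
    and pathway p-values are BH-adjusted across TFs.  With several
    treatments, ``focus_treatment`` defaults to the last one listed.
    """
    if isinstance(treatments, str):
        treatments = [treatments]
    if focus_treatment is None:
        focus_treatment = treatments[-1]
    conditions = [control, *treatments]
    cond_arr = np.array([expr.condition_of(c) for c in expr.column_ids])
    masks = {cond: cond_arr == cond for cond in conditions}
    for cond in conditions:
        if not masks[cond].any():
            raise ValueError(f"no cells in condition {cond!r}")
    acc = accessibility[list(expr.column_ids)]

    results: list[TFLinkageResult] = []
    for t, tf in enumerate(acc.index):
        if tf not in targets:
            raise ValueError(f"TF {tf!r} has no target list")
        a = acc.loc[tf].to_numpy(dtype=float)
        score = module_score(
            expr, targets[tf], n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + t
        )
        diff = float(
            a[masks[focus_treatment]].mean() - a[masks[control]].mean()
        )
        broad_p = float(
            mannwhitneyu(
                score[masks[focus_treatment]], score[masks[control]],
                alternative="greater", method="asymptotic",
            ).pvalue
        )
        pathway_targets = [g for g in targets[tf] if g in set(pathway_set)]
        if pathway_targets:
            pscore = module_score(
                expr, pathway_targets, n_bins=n_bins, n_ctrl=n_ctrl,
                seed=seed + t,
            )
            pathway_p = float(
                mannwhitneyu(
                    pscore[masks[focus_treatment]], pscore[masks[control]],
                    alternative="greater", method="asymptotic",
                ).pvalue
            )
        else:
            pathway_p = float("nan")
        r2 = {}
        for cond in conditions:
            try:
                r2[cond] = tf_target_r2(a, score, masks[cond])
            except ValueError:
                r2[cond] = float("nan")
        valid = {c: v for c, v in r2.items() if not np.isnan(v)}
        dr2 = (
            delta_r2(valid, control)
            if control in valid
            else {c: float("nan") for c in treatments}
        )
        dr2 = {c: dr2.get(c, float("nan")) for c in treatments}
        results.append(
            TFLinkageResult(
                tf=str(tf), accessibility_diff=diff, broad_p=broad_p,
                pathway_p=pathway_p, r2_by_condition=r2, delta_r2=dr2,
            )
        )
    broad_adj = adjust_bh([r.broad_p for r in results])
    for r, pa in zip(results, broad_adj):
        r.broad_p_adj = float(pa)
    with_pathway = [r for r in results if not np.isnan(r.pathway_p)]
    if with_pathway:
        path_adj = adjust_bh([r.pathway_p for r in with_pathway])
        for r, pa in zip(with_pathway, path_adj):
            r.pathway_p_adj = float(pa)
    return results


def linkage_to_frame(results: Sequence[TFLinkageResult]) -> pd.DataFrame:
    """Tabulate TF linkage results, one row per TF."""
    rows = []
    for r in results:
        row = {
            "tf": r.tf,
            "accessibility_diff": r.accessibility_diff,
            "broad_p": r.broad_p, "broad_p_adj": r.broad_p_adj,
            "pathway_p": r.pathway_p, "pathway_p_adj": r.pathway_p_adj,
        }
        for cond, v in r.r2_by_condition.items():
            row[f"r2_{cond}"] = v
        for cond, v in r.delta_r2.items():
            row[f"delta_r2_{cond}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("tf")
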