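"""Associate identities with orthogonal phenotypes.

Group-vs-rest rank-sum tests (expression, CRISPR gene-effect, drug AUC),
Pearson correlations between per-identity sample weights (H z-scores) and
drug AUC, hallmark gene-set overlap fractions, attribution of differential
genes to identities, and chi-squared enrichment of drug classes among
drugs with differential response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import linregress, mannwhitneyu, pearsonr
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "group_vs_rest_wilcoxon",
    "adjust_bh",
    "identity_drug_correlation",
    "hallmark_overlap",
    "deg_identity_attribution",
    "drug_class_enrichment",
]


@dataclass
class AssociationResult:
    """One association record (for tabular export)."""

    kind: str
    feature: str
    statistic: float
    p_value: float
    p_adjusted: float = float("nan")
    effect: float = float("nan")


def group_vs_rest_wilcoxon(
    values: Mapping[str, float],
    group: Iterable[str],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) of a sample group versus the rest.

    The exact null distribution is enumerated when both sides have <= 8
    observations and there are no ties; otherwise the tie-corrected normal
    approximation (with continuity correction) is used.  Returns (U for the
    group side, p).
    """
    group = set(group)
    x = np.array([v for s, v in values.items() if s in group], dtype=float)
    y = np.array([v for s, v in values.items() if s not in group], dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both the group and the rest must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


class CorrelationResult(NamedTuple):
    pcc: float
    p_value: float
    slope: float
    intercept: float
    n: int


def identity_drug_correlation(
    identity_z: Mapping[str, float],
    auc: Mapping[str, float],
) -> CorrelationResult:
    """Pearson correlation of a factor's sample z-scores with drug AUC.

    Computed on the overlapping samples (>= 3 required) with a two-sided
    t-test p and an OLS fit; zero variance on either side yields a flagged
    NaN result instead of an error.
    """
    common = [s for s in identity_z if s in auc]
    if len(common) < 3:
        raise ValueError(f"need >= 3 overlapping samples, got {len(common)}")
    x = np.array([identity_z[s] for s in common], dtype=float)
    y = np.array([auc[s] for s in common], dtype=float)
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        logger.warning("zero variance in correlation input; PCC undefined")
        nan = float("nan")
        return CorrelationResult(nan, nan, nan, nan, len(common))
    r, p = pearsonr(x, y)
    fit = linregress(x, y)
    return CorrelationResult(float(r), float(p), float(fit.slope),
                             float(fit.intercept), len(common))


def hallmark_overlap(
    identity_genes: Iterable[str],
    collection: GeneSetCollection,
) -> dict[str, float]:
    """Fraction of an identity's genes found in each reference gene set."""
    identity = set(identity_genes)
    if not identity:
        raise ValueError("identity gene set is empty")
    return {
        name: len(identity & set(genes)) / len(identity)
        for name, genes in collection.sets.items()
    }


def deg_identity_attribution(
    degs: Mapping[str, Iterable[str]],
    gene_groups: Mapping[str, str],
) -> dict[str, dict[str, float]]:
    """Per-direction proportions of differential genes per identity.

    ``degs`` maps a direction ("up"/"down") to its gene list; genes outside
    the salient gene groups count as "other".  Proportions sum to 1 within
    each direction; an empty direction yields an empty dict with a warning.
    """
    out: dict[str, dict[str, float]] = {}
    for direction, genes in degs.items():
        genes = list(genes)
        if not genes:
            logger.warning("no differential genes in direction %r", direction)
            out[direction] = {}
            continue
        counts: dict[str, int] = {}
        for g in genes:
            ident = gene_groups.get(g, "other")
            counts[ident] = counts.get(ident, 0) + 1
        out[direction] = {i: c / len(genes) for i, c in counts.items()}
    return out


def _chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Uncorrected 2x2 chi-squared; degenerate margins give (0, 1)."""
    O = np.asarray(table, dtype=float)
    row, col = O.sum(axis=1), O.sum(axis=0)
    N = O.sum()
    if (row == 0).any() or (col == 0).any() or N == 0:
        return 0.0, 1.0
    E = np.outer(row, col) / N
    stat = float(((O - E) ** 2 / E).sum())
    return stat, float(chi2_dist.sf(stat, 1))


def drug_class_enrichment(
    auc: pd.DataFrame,
    drug_classes: Mapping[str, str],
    tnbc_samples: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Which drug classes are enriched for differential response?

    Per drug, a two-sided rank-sum test compares AUC in the disease-group
    samples versus the rest, BH-adjusted over drugs; drugs with adjusted
    p < ``alpha`` are flagged "differential".  Per class (>= 2 drugs), a
    2x2 chi-squared of {in class} x {differential} is computed and
    BH-adjusted across classes.  Returns one row per class with counts,
    chi2, p and adjusted p.
    """
    tnbc = set(tnbc_samples)
    if not tnbc or not (set(auc.columns) - tnbc):
        raise ValueError("both sample groups must be non-empty")
    drugs = list(auc.index)
    pvals = []
    for d in drugs:
        _, p = group_vs_rest_wilcoxon(auc.loc[d].to_dict(), tnbc)
        pvals.append(p)
    p_adj = adjust_bh(pvals)
    differential = {d: pa < alpha for d, pa in zip(drugs, p_adj)}

    classes = sorted({drug_classes[d] for d in drugs if d in drug_classes})
    rows = []
    for cls in classes:
        in_cls = [d for d in drugs if drug_classes.get(d) == cls]
        if len(in_cls) < 2:
            logger.warning("skipping class %r with < 2 drugs", cls)
            continue
        out_cls = [d for d in drugs if drug_classes.get(d) != cls]
        a = sum(differential[d] for d in in_cls)
        b = len(in_cls) - a
        c = sum(differential[d] for d in out_cls)
        dd = len(out_cls) - c
        stat, p = _chi2_2x2(np.array([[a, b], [c, dd]]))
        frac_in = a / len(in_cls)
        frac_out = c / len(out_cls) if out_cls else 0.0
        rows.append({
            "drug_class": cls, "n_drugs": len(in_cls), "n_differential": a,
            "chi2": stat, "p_value": p,
            "enrichment": frac_in - frac_out,
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["p_adjusted"] = adjust_bh(result["p_value"].to_numpy())
        result = result.set_index("drug_class")
    return result
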