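# scidentity

Tumor cell populations are heterogeneous: subpopulations with distinct
transcriptional programs respond to drug treatment in different ways, and
the few that expand under therapy drive resistance. `scidentity` implements
a bulk-to-single-cell "identity" framework for studying this: latent
transcriptional programs are discovered in bulk expression cohorts, each
single cell in a treated/untreated experiment is scored against those
programs, and composition shifts between conditions are quantified and
attributed to cell clusters, drug phenotypes and transcription-factor
activity. It is written for computational biologists analyzing paired bulk
and single-cell (multi)omics data, e.g. in triple-negative breast cancer.

## The method

1. **Salient gene selection.** Every candidate gene *g* is paired with a
   fixed anchor gene (MYC by default) and the samples become 2-D points
   (x<sub>g</sub>, x<sub>MYC</sub>) in log-expression space. DBSCAN is run
   over an eps grid (0.10-1.21, step 0.01); *g* is *salient* if at least
   one eps yields a cluster pair that is large enough, has centroid
   distance above a floor, and (for cell-line cohorts) a single-linkage
   gap above 1. A two-round variant handles tumor cohorts, counting
   basal-like samples per cluster.
2. **Identity discovery.** On the salient-gene matrix X (genes x samples),
   non-negative matrix factorization X ~ W H is fit over a rank grid
   (best-of-restarts, Frobenius loss); the rank k* is the elbow (maximum
   discrete curvature) of the reconstruction-error curve. Ward clustering
   of the normalized H columns groups samples into identities F0..F(k-1);
   genes join the identity of their largest W weight.
3. **Single-cell mapping ("reverse NMF").** With W fixed, each cell's
   expression x solves min ||x - W h||, h >= 0 (NNLS); the argmax of h is
   the cell's identity and pooled z-scores of h give per-identity
   intensity scores.
4. **Shift analysis.** Identity x condition cell counts feed a chi-squared
   test; the Pearson residual (O - E)/sqrt(E) of the treated column is each
   identity's *residual score* (positive = expansion). The same residuals,
   restricted to the expanded identity and cross-tabulated by cell
   cluster, apportion the expansion to clusters.
5. **Phenotype association.** Group-vs-rest Wilcoxon rank-sum tests
   (expression, CRISPR gene effect, drug AUC), Pearson correlation of drug
   AUC with H z-scores, hallmark gene-set overlap fractions, DEG-to-identity
   attribution and drug-class enrichment (BH-adjusted throughout).
6. **TF linkage.** Per-cell gene-set module scores (set mean minus
   expression-bin-matched controls) are regressed on TF motif
   accessibility per condition; the change in R-squared after treatment
   (delta R^2) nominates treatment-activated regulators.

A synthetic-data module generates bulk cohorts, single cells, drug-AUC
tables and accessibility/expression pairs with known ground truth, so every
stage has a parameter-recovery test surface without any download.

## Worked example

```python
import scidentity as sid

bulk, truth = sid.generate_bulk(seed=1)          # 400 genes x 40 samples, k=4
salient = sid.select_salient_genes(bulk)
model = sid.fit_identity_model(bulk.subset_genes(salient.genes),
                               k_grid=range(2, 9), seed=1)
cells, _ = sid.generate_single_cells(truth, seed=1)
profiles = sid.map_cells(cells, model)
table = sid.identity_contingency(profiles, ("control", "treated"))
result = sid.chisq_residuals(table)
```

Running `examples/01_discover_identities.py` and `examples/03_quantify_shift.py`
prints:

```
salient genes: 200 (anchor MYC included)
elbow-selected rank k* = 4
samples per identity: {'F2': 10, 'F3': 10, 'F0': 10, 'F1': 10}

    control  treated
F0      121       95
F1      131       97
F2      131       96
F3      117      212
chi2 = 41.03, dof = 3, p = 6.45e-09
  residual score F3: +3.70
most expanded identity: F3
```

The 200 selected genes are exactly the planted program markers, the elbow
recovers the planted rank 4, each sample joins its generating program, and
the identity whose composition was shifted +15% in the treated condition
gets the largest positive residual score with a decisive chi-squared
p-value. The other examples cover drug-AUC correlation
(`04_drug_associations.py`: the coupled drug tops the list at the planted
|PCC| of 0.93) and TF linkage (`05_tf_linkage.py`: the planted TF shows
treated R^2 of 0.51 against the closed-form 0.5 and ranks first by delta
R^2 among 20 decoys).

A thin CLI mirrors the stages (`scidentity simulate | select-genes | fit |
map | run --config run.yaml`); see `scidentity --help`.

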