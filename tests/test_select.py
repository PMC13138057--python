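"""Anchor-paired DBSCAN gene selection: prefilters, clustering semantics,
acceptance rules and the sklearn cross-check."""

import numpy as np
import pytest
from sklearn.cluster import DBSCAN

import scidentity as sid
from scidentity.select import GeneSelectionConfig, _scan_eps_grid


def blob(center, n, rng, sd=0.1):
    return rng.normal(center, sd, size=(n, 2))


class TestPrefilter:
    @pytest.mark.parametrize(
        "values, kept",
        [
            ([0.0, 2.9], False),   # max below the expression floor
            ([0.0, 3.0], True),    # boundary values survive (strict removal)
            ([5.0, 6.0], False),   # range too small
            ([0.5, 4.0], True),
        ],
    )
    def test_threshold_semantics(self, values, kept):
        expr = sid.ExpressionMatrix(
            np.array([values, [0.0, 8.0]]), ["g1", "MYC"], ["A", "B"]
        )
        survivors = sid.prefilter_genes(expr, GeneSelectionConfig())
        assert ("g1" in survivors) == kept

    def test_anchor_must_survive(self):
        expr = sid.ExpressionMatrix(
            np.array([[0.0, 5.0], [1.0, 1.5]]), ["g1", "MYC"], ["A", "B"]
        )
        with pytest.raises(ValueError, match="anchor"):
            sid.prefilter_genes(expr, GeneSelectionConfig())


class TestDbscanPair:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([blob([0, 0], 5, rng), blob([10, 10], 5, rng)])
        labels = sid.dbscan_pair(pts[:, 0], pts[:, 1], eps=0.5, min_samples=3)
        assert sorted(np.unique(labels)) == [0, 1]
        assert (labels[:5] == labels[0]).all() and (labels[5:] == labels[5]).all()

    def test_identical_points_one_cluster(self):
        v = np.zeros(8)
        labels = sid.dbscan_pair(v, v, eps=0.5, min_samples=3)
        assert (labels == 0).all()

    def test_sparse_collinear_points_all_noise(self):
        x = np.arange(12.0)
        labels = sid.dbscan_pair(x, np.zeros(12), eps=0.5, min_samples=3)
        assert (labels == -1).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_sklearn_oracle(self, seed):
        """Cross-check against sklearn DBSCAN on random 2-D instances.

        Noise sets and core-point partitions must agree exactly; border
        points (non-core within eps of a core) may be claimed by either
        adjacent cluster, so they are checked for cluster validity only.
        """
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        pts = rng.uniform(0, 4, size=(n, 2))
        eps = float(rng.uniform(0.2, 1.2))
        min_samples = int(rng.integers(2, 6))
        ours = sid.dbscan_pair(pts[:, 0], pts[:, 1], eps, min_samples)
        ref = DBSCAN(eps=eps, min_samples=min_samples).fit(pts).labels_
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        core = (d <= eps).sum(axis=1) >= min_samples
        assert ((ours == -1) == (ref == -1)).all()
        # core partition: co-membership must match
        ci = np.nonzero(core)[0]
        same_ours = ours[ci][:, None] == ours[ci][None]
        same_ref = ref[ci][:, None] == ref[ci][None]
        assert (same_ours == same_ref).all()
        # border points must sit within eps of a core of their own cluster
        for i in np.nonzero(~core & (ours != -1))[0]:
            assert any(core[j] and ours[j] == ours[i] and d[i, j] <= eps
                       for j in range(n))


class TestEvaluateGene:
    def test_eps_grid_has_112_values(self):
        grid = GeneSelectionConfig().eps_grid
        assert len(grid) == 112
        assert grid[0] == pytest.approx(0.1) and grid[-1] == pytest.approx(1.21)

    def test_clear_pair_accepted(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([blob([0, 0], 5, rng), blob([4, 4], 5, rng)])
        ev = sid.evaluate_gene(pts[:, 0], pts[:, 1], GeneSelectionConfig())
        assert ev is not None
        assert ev["best_pair_centroid_dist"] > 3
        assert ev["separation"] > 1

    def test_size_rule_is_strict(self):
        # clusters of exactly 3 are not "more than 3"
        rng = np.random.default_rng(1)
        pts = np.vstack([blob([0, 0], 3, rng), blob([4, 4], 3, rng)])
        assert sid.evaluate_gene(pts[:, 0], pts[:, 1], GeneSelectionConfig()) is None

    def test_tumor_counts_are_non_strict(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([blob([0, 0], 10, rng), blob([6, 6], 10, rng)])
        cfg = GeneSelectionConfig(mode="tumor_two_round")
        ev = _scan_eps_grid(
            pts, cfg.eps_grid, cfg.min_samples,
            cfg.tumor_round1_min_cluster, size_strict=False,
            min_centroid_dist=cfg.tumor_min_centroid_dist, min_separation=None,
        )
        assert ev is not None and ev["best_pair_min_sizes"][0] == 10


class TestSelectSalientGenes:
    def test_recovers_planted_markers(self, bulk_truth, salient):
        _, truth = bulk_truth
        markers = {g for b in truth.marker_blocks.values() for g in b}
        selected = set(salient.genes)
        assert truth.anchor_gene in selected
        assert len(selected & markers) / len(markers) >= 0.95
        noise_genes = set(truth.gene_ids) - markers
        false_pos = len(selected & noise_genes) / len(noise_genes)
        assert false_pos <= 0.05

    def test_evidence_present_for_every_non_anchor_gene(self, salient):
        for g in salient.genes[1:]:
            ev = salient.per_gene_evidence[g]
            assert set(ev) == {"best_eps", "best_pair_centroid_dist",
                               "best_pair_min_sizes", "separation"}

    def test_impossible_thresholds_error(self, bulk_truth):
        bulk, _ = bulk_truth
        cfg = GeneSelectionConfig(min_centroid_dist=np.inf)
        with pytest.raises(ValueError, match="no gene passed"):
            sid.select_salient_genes(bulk, cfg)

    def test_invariant_to_sample_and_gene_order(self, bulk_truth):
        bulk, _ = bulk_truth
        sub = bulk.subset_genes(bulk.gene_ids[:30])  # anchor is gene 0
        base = sid.select_salient_genes(sub)
        rng = np.random.default_rng(0)
        cols = list(rng.permutation(sub.column_ids))
        genes = [sub.gene_ids[i] for i in rng.permutation(len(sub.gene_ids))]
        shuffled = sub.subset_columns(cols).subset_genes(genes)
        again = sid.select_salient_genes(shuffled)
        assert base.genes == again.genes

    def test_monotone_in_centroid_threshold(self, bulk_truth):
        bulk, _ = bulk_truth
        sub = bulk.subset_genes(bulk.gene_ids[:30])
        loose = sid.select_salient_genes(sub, GeneSelectionConfig())
        tight = sid.select_salient_genes(
            sub, GeneSelectionConfig(min_centroid_dist=5.0)
        )
        assert set(tight.genes) <= set(loose.genes)

    def test_tumor_two_round_mode(self, bulk_truth):
        bulk, truth = bulk_truth
        sub = bulk.subset_genes(bulk.gene_ids[:40])
        basal = sub.column_ids  # every sample counts as basal here
        result = sid.select_salient_genes(
            sub, GeneSelectionConfig(mode="tumor_two_round"), basal_samples=basal
        )
        assert result.genes[0] == truth.anchor_gene
        for ev in result.per_gene_evidence.values():
            assert ev["best_pair_centroid_dist"] > 4
            assert ev["best_pair_min_sizes"][0] >= 8

    def test_tumor_mode_requires_basal_samples(self, bulk_truth):
        bulk, _ = bulk_truth
        with pytest.raises(ValueError, match="basal"):
            sid.select_salient_genes(
                bulk, GeneSelectionConfig(mode="tumor_two_round")
            )
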