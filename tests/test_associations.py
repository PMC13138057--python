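"""Phenotype associations: rank tests, BH, correlations, overlaps, enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import scidentity as sid


def exact_ranksum_p(x, y):
    """Full enumeration of rank assignments (no ties) for a two-sided test."""
    pooled = sorted(x) + sorted(y)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    rx = sum(ranks[v] for v in x)
    n, m = len(x), len(y)
    all_sums = [sum(c) for c in combinations(range(1, n + m + 1), n)]
    mean = n * (n + m + 1) / 2
    extreme = sum(abs(s - mean) >= abs(rx - mean) - 1e-12 for s in all_sums)
    return extreme / len(all_sums)


class TestGroupVsRestWilcoxon:
    def test_exact_small_sample_worked_example(self):
        values = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6}
        _, p = sid.group_vs_rest_wilcoxon(values, {"a", "b", "c"})
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        values = {f"s{i}": v for i, v in enumerate([1, 2, 3, 1, 2, 3])}
        _, p = sid.group_vs_rest_wilcoxon(values, {"s0", "s1", "s2"})
        assert p == pytest.approx(1.0)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=12)
        values = {f"s{i}": v for i, v in enumerate(vals)}
        group = {f"s{i}" for i in range(5)}
        _, p1 = sid.group_vs_rest_wilcoxon(values, group)
        _, p2 = sid.group_vs_rest_wilcoxon(
            {k: np.exp(3 * v) for k, v in values.items()}, group
        )
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_full_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 11 - n))
        vals = rng.permutation(np.arange(n + m, dtype=float) * 1.7 + 0.3)
        values = {f"s{i}": v for i, v in enumerate(vals)}
        group = {f"s{i}" for i in range(n)}
        _, p = sid.group_vs_rest_wilcoxon(values, group)
        assert p == pytest.approx(
            exact_ranksum_p(vals[:n].tolist(), vals[n:].tolist()), abs=1e-12
        )

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sid.group_vs_rest_wilcoxon({"a": 1.0}, {"a"})


class TestAdjustBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            sid.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sid.adjust_bh([0.2]), [0.2])

    def test_matches_textbook_step_up(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        adj = sid.adjust_bh(p)
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        cummin = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            cummin = min(cummin, p[i] * m / rank)
            manual[i] = cummin
        np.testing.assert_allclose(adj, manual, atol=1e-12)
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()


class TestIdentityDrugCorrelation:
    def test_exact_linear_relationship(self):
        z = {f"s{i}": float(i) for i in range(6)}
        auc = {s: 2 * v + 1 for s, v in z.items()}
        res = sid.identity_drug_correlation(z, auc)
        assert res.pcc == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_anticorrelation(self):
        z = {f"s{i}": float(i) for i in range(5)}
        res = sid.identity_drug_correlation(z, {s: -v for s, v in z.items()})
        assert res.pcc == pytest.approx(-1.0)

    def test_zero_variance_flagged_not_crashed(self, caplog):
        z = {f"s{i}": 1.0 for i in range(5)}
        auc = {f"s{i}": float(i) for i in range(5)}
        with caplog.at_level("WARNING"):
            res = sid.identity_drug_correlation(z, auc)
        assert np.isnan(res.pcc)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 30))
        res = sid.identity_drug_correlation(
            {f"s{i}": v for i, v in enumerate(x)},
            {f"s{i}": v for i, v in enumerate(y)},
        )
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.pcc == pytest.approx(manual, abs=1e-12)

    def test_planted_drug_coupling_recovered(self, bulk_truth, model, factor_map):
        _, truth = bulk_truth
        drugs = sid.generate_drug_table(truth, seed=1)
        eff = truth.drug_effect
        planted_pcc = eff["slope"] / np.hypot(eff["slope"], eff["noise_sd"])
        target = truth.identity_names[eff["factor_index"]]
        factor = next(f for f, t in factor_map.items() if t == target)
        z = dict(zip(
            model.sample_ids,
            model.H_zscores[model.factor_names.index(factor)],
        ))
        res = sid.identity_drug_correlation(z, drugs.loc[eff["drug"]].to_dict())
        assert abs(abs(res.pcc) - abs(planted_pcc)) < 0.1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 overlapping"):
            sid.identity_drug_correlation({"a": 1.0, "b": 2.0},
                                          {"a": 1.0, "b": 2.0})


class TestHallmarkOverlap:
    def test_fractions(self):
        coll = sid.GeneSetCollection({
            "H1": ["g1", "g2", "x1"], "H2": ["y1"],
            "H3": [f"g{i}" for i in range(1, 11)],
        })
        identity = [f"g{i}" for i in range(1, 11)]
        out = sid.hallmark_overlap(identity, coll)
        assert out["H1"] == pytest.approx(0.2)
        assert out["H2"] == 0.0
        assert out["H3"] == 1.0


class TestDegAttribution:
    def test_proportions_per_direction(self):
        groups = {"g1": "F2", "g2": "F2", "g3": "F1"}
        out = sid.deg_identity_attribution(
            {"up": ["g1", "g2", "g3"], "down": ["q1", "q2"]}, groups
        )
        assert out["up"] == pytest.approx({"F2": 2 / 3, "F1": 1 / 3})
        assert out["down"] == {"other": 1.0}
        for d in out.values():
            assert sum(d.values()) == pytest.approx(1.0)

    def test_empty_direction_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = sid.deg_identity_attribution({"up": []}, {})
        assert out["up"] == {}


class TestDrugClassEnrichment:
    def _table(self, effects, n_samples=24, seed=0):
        """Drugs x samples AUC; TNBC samples get `effects[drug]` added."""
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n_samples)]
        tnbc = set(samples[: n_samples // 2])
        rows = {}
        for drug, eff in effects.items():
            base = rng.normal(0.5, 0.02, size=n_samples)
            base[: n_samples // 2] += eff
            rows[drug] = base
        return pd.DataFrame(rows, index=samples).T, tnbc

    def test_concentrated_class_is_top_hit(self):
        effects = {f"epi{i}": 0.3 for i in range(4)}
        effects.update({f"other{i}": 0.0 for i in range(8)})
        auc, tnbc = self._table(effects)
        classes = {d: ("epigenetic" if d.startswith("epi") else "kinase")
                   for d in auc.index}
        res = sid.drug_class_enrichment(auc, classes, tnbc)
        assert res.loc["epigenetic", "n_differential"] == 4
        assert res.loc["epigenetic", "p_adjusted"] == res["p_adjusted"].min()
        assert res.loc["epigenetic", "enrichment"] > 0

    def test_no_differential_drugs_gives_zero_chi2(self):
        effects = {f"d{i}": 0.0 for i in range(8)}
        auc, tnbc = self._table(effects)
        classes = {d: ("A" if i < 4 else "B") for i, d in enumerate(auc.index)}
        res = sid.drug_class_enrichment(auc, classes, tnbc)
        assert (res["chi2"] == 0).all()
        assert (res["p_value"] == 1).all()

    def test_small_class_skipped(self, caplog):
        effects = {f"d{i}": 0.0 for i in range(5)}
        auc, tnbc = self._table(effects)
        classes = {d: ("solo" if i == 0 else "B") for i, d in enumerate(auc.index)}
        with caplog.at_level("WARNING"):
            res = sid.drug_class_enrichment(auc, classes, tnbc)
        assert "solo" not in res.index
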