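"""Chi-squared identity-shift analysis and cluster contributions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import scidentity as sid
from scidentity.mapping import CellIdentityProfile


def make_profiles(spec):
    """spec: list of (identity, condition, cluster, n)."""
    out = []
    i = 0
    for ident, cond, clust, n in spec:
        for _ in range(n):
            out.append(CellIdentityProfile(
                cell_id=f"c{i}", h=np.array([1.0]), assigned_identity=ident,
                identity_scores=np.array([0.0]), condition=cond, cluster=clust,
            ))
            i += 1
    return out


class TestIdentityContingency:
    def test_single_identity_two_conditions(self):
        profiles = make_profiles(
            [("F0", "pre", "", 10), ("F0", "post", "", 10)]
        )
        table = sid.identity_contingency(profiles, ("pre", "post"))
        assert table.shape == (1, 2)
        np.testing.assert_array_equal(table.to_numpy(), [[10, 10]])

    def test_total_equals_assigned_cells(self):
        profiles = make_profiles([
            ("F0", "pre", "", 5), ("F1", "pre", "", 3), ("F2", "pre", "", 2),
            ("F0", "post", "", 1), ("F1", "post", "", 7), ("F2", "post", "", 4),
            ("unassigned", "post", "", 3),
        ])
        table = sid.identity_contingency(profiles, ("pre", "post"))
        assert table.shape == (3, 2)
        assert table.to_numpy().sum() == 22  # unassigned excluded

    def test_identity_absent_post_keeps_zero_column(self):
        profiles = make_profiles(
            [("F0", "pre", "", 5), ("F1", "pre", "", 5), ("F1", "post", "", 5)]
        )
        table = sid.identity_contingency(profiles, ("pre", "post"))
        assert table.loc["F0", "post"] == 0

    def test_empty_condition_rejected(self):
        profiles = make_profiles([("F0", "pre", "", 5)])
        with pytest.raises(ValueError, match="0 assigned cells"):
            sid.identity_contingency(profiles, ("pre", "post"))


class TestChisqResiduals:
    def test_balanced_table_is_null(self):
        table = pd.DataFrame([[50, 50], [50, 50]], index=["F0", "F1"],
                             columns=["pre", "post"])
        res = sid.chisq_residuals(table)
        assert res.chi2 == 0.0
        np.testing.assert_array_equal(res.residuals.to_numpy(), 0.0)

    def test_hand_worked_table(self):
        table = pd.DataFrame([[60, 40], [40, 60]], index=["F0", "F1"],
                             columns=["pre", "post"])
        res = sid.chisq_residuals(table)
        assert res.chi2 == pytest.approx(8.0)
        assert res.dof == 1
        np.testing.assert_allclose(
            np.abs(res.residuals.to_numpy()), 10 / np.sqrt(50)
        )
        assert res.residual_scores["F1"] == pytest.approx(np.sqrt(2), abs=1e-4)
        assert res.most_expanded == "F1"

    def test_count_scaling_law(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(5, 50, size=(3, 2)) * 1.0,
                         columns=["a", "b"])
        r1 = sid.chisq_residuals(t)
        r2 = sid.chisq_residuals(2 * t)
        assert r2.chi2 == pytest.approx(2 * r1.chi2, rel=1e-12)
        np.testing.assert_allclose(
            r2.residuals.to_numpy(), np.sqrt(2) * r1.residuals.to_numpy()
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 6)), int(rng.integers(2, 4)))
        t = pd.DataFrame(rng.integers(1, 80, size=shape) * 1.0)
        res = sid.chisq_residuals(t)
        stat, p, dof, expected = chi2_contingency(t.to_numpy(), correction=False)
        assert res.chi2 == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.dof == dof
        np.testing.assert_allclose(
            res.residuals.to_numpy(),
            (t.to_numpy() - expected) / np.sqrt(expected),
            atol=1e-10,
        )

    def test_margin_sums_of_deviations_vanish(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.integers(1, 30, size=(4, 3)) * 1.0)
        res = sid.chisq_residuals(t)
        O = t.to_numpy()
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        np.testing.assert_allclose((O - E).sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose((O - E).sum(axis=0), 0.0, atol=1e-10)

    def test_zero_margin_names_the_offender(self):
        t = pd.DataFrame([[0, 0], [5, 5]], index=["F0", "F1"],
                         columns=["pre", "post"])
        with pytest.raises(ValueError, match="F0"):
            sid.chisq_residuals(t)

    def test_standardized_residuals_option(self):
        t = pd.DataFrame([[60, 40], [40, 60]], columns=["pre", "post"])
        pearson = sid.chisq_residuals(t).residuals.to_numpy()
        standardized = sid.chisq_residuals(
            t, residual_type="standardized"
        ).residuals.to_numpy()
        adj = np.sqrt(0.5 * 0.5)  # margins are all N/2
        np.testing.assert_allclose(standardized, pearson / adj)


class TestClusterContributions:
    def test_concentrated_expansion_ranks_the_cluster_first(self):
        profiles = make_profiles([
            ("F2", "pre", "c0", 20), ("F2", "pre", "c1", 20),
            ("F2", "post", "c0", 60), ("F2", "post", "c1", 20),
        ])
        res = sid.cluster_contributions(profiles, "F2", ("pre", "post"))
        assert res.most_expanded == "c0"
        assert res.residual_scores["c0"] > 0 > res.residual_scores["c1"]

    def test_proportional_scaling_gives_null_residuals(self):
        profiles = make_profiles([
            ("F2", "pre", "c0", 10), ("F2", "pre", "c1", 30),
            ("F2", "post", "c0", 20), ("F2", "post", "c1", 60),
        ])
        res = sid.cluster_contributions(profiles, "F2", ("pre", "post"))
        np.testing.assert_allclose(res.residuals.to_numpy(), 0.0, atol=1e-10)

    def test_residuals_invariant_to_cluster_relabeling(self):
        spec = [
            ("F2", "pre", "c0", 10), ("F2", "pre", "c1", 30),
            ("F2", "post", "c0", 40), ("F2", "post", "c1", 35),
        ]
        res1 = sid.cluster_contributions(make_profiles(spec), "F2", ("pre", "post"))
        renamed = [
            (i, c, {"c0": "z9", "c1": "a1"}[cl], n) for i, c, cl, n in spec
        ]
        res2 = sid.cluster_contributions(make_profiles(renamed), "F2", ("pre", "post"))
        assert res1.residual_scores["c0"] == pytest.approx(
            res2.residual_scores["z9"]
        )
        assert res1.residual_scores["c1"] == pytest.approx(
            res2.residual_scores["a1"]
        )

    def test_single_cluster_rejected(self):
        profiles = make_profiles(
            [("F2", "pre", "c0", 10), ("F2", "post", "c0", 20)]
        )
        with pytest.raises(ValueError, match="2 clusters"):
            sid.cluster_contributions(profiles, "F2", ("pre", "post"))


class TestPlantedShiftRecovery:
    def test_planted_expansion_is_most_expanded(self, profiles, factor_map):
        """The +0.15 composition shift toward planted F0 must surface as the
        most-expanded identity with a significant chi-squared test."""
        table = sid.identity_contingency(profiles, ("control", "treated"))
        res = sid.chisq_residuals(table)
        assert factor_map[res.most_expanded] == "F0"
        assert res.p_value < 0.01
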