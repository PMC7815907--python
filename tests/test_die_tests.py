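import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isodie.die_tests import adjust_bh, adjust_by, chi2_nx2, delta_pi, exon_test_eligible
from isodie.die_tests import test_exons as exon_usage_test
from isodie.die_tests import test_feature_usage as feature_usage_test
from isodie.isoform_catalog import UsageTable


def pearson_2x2(a, b, c, d):
    """Closed-form Pearson statistic for a 2x2 table."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestChi2:
    def test_worked_example(self):
        from scipy.stats import chi2 as chi2_dist

        p = chi2_nx2([[30, 10], [10, 30]])
        stat = pearson_2x2(30, 10, 10, 30)
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(chi2_dist.sf(20.0, 1), rel=1e-9)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_identical_rows_give_p_one(self):
        assert chi2_nx2([[10, 10], [10, 10]]) == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        t = [[5, 9], [12, 3], [7, 7]]
        assert chi2_nx2(t) == pytest.approx(chi2_nx2(t[::-1]))

    def test_zero_rows_dropped_zero_column_untestable(self):
        assert chi2_nx2([[5, 9], [0, 0], [12, 3]]) == pytest.approx(chi2_nx2([[5, 9], [12, 3]]))
        with pytest.raises(ValueError):
            chi2_nx2([[5, 0], [12, 0]])
        with pytest.raises(ValueError):
            chi2_nx2([[5, 9]])

    @given(
        st.tuples(
            st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50)
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_closed_form_on_2x2(self, cells):
        from scipy.stats import chi2 as chi2_dist

        a, b, c, d = cells
        expected = chi2_dist.sf(pearson_2x2(a, b, c, d), 1)
        assert chi2_nx2([[a, b], [c, d]]) == pytest.approx(expected, rel=1e-9, abs=1e-300)


class TestDeltaPi:
    def test_single_isoform_contribution(self):
        a = pd.Series({"x": 0.5, "y": 0.3, "z": 0.2})
        b = pd.Series({"x": 0.2, "y": 0.3, "z": 0.5})
        dpi, contrib = delta_pi(a, b)
        assert dpi == pytest.approx(0.3)
        assert [c[0] for c in contrib] == ["x"]

    def test_two_isoform_same_direction_sum(self):
        a = pd.Series({"w": 0.4, "x": 0.4, "y": 0.1, "z": 0.1})
        b = pd.Series({"w": 0.25, "x": 0.25, "y": 0.25, "z": 0.25})
        dpi, contrib = delta_pi(a, b)
        assert dpi == pytest.approx(0.3)
        assert sorted(c[0] for c in contrib) == ["w", "x"]

    def test_identical_distributions_give_zero(self):
        a = pd.Series({"x": 0.6, "y": 0.4})
        dpi, contrib = delta_pi(a, a)
        assert dpi == 0.0 and contrib == []

    def test_negative_direction_reported_with_sign(self):
        # one concentrated loss vs four small gains: downward pair dominates
        a = pd.Series({"v": 0.2, "w": 0.2, "x": 0.2, "y": 0.2, "z": 0.2})
        b = pd.Series({"v": 0.1, "w": 0.1, "x": 0.1, "y": 0.1, "z": 0.6})
        dpi, contrib = delta_pi(a, b)
        assert dpi == pytest.approx(-0.4)
        assert [c[0] for c in contrib] == ["z"]

    def test_antisymmetric_in_groups(self):
        rng = np.random.default_rng(3)
        v1 = rng.dirichlet(np.ones(5))
        v2 = rng.dirichlet(np.ones(5))
        a = pd.Series(v1, index=list("abcde"))
        b = pd.Series(v2, index=list("abcde"))
        assert delta_pi(a, b)[0] == pytest.approx(-delta_pi(b, a)[0])


class TestAdjustments:
    def test_bh_step_up_worked_example(self):
        adj, _ = adjust_bh([0.01, 0.02, 0.03])
        assert adj.tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_by_adds_harmonic_factor(self):
        adj, _ = adjust_by([0.01, 0.02, 0.03])
        assert adj.tolist() == pytest.approx([0.055, 0.055, 0.055])  # c(3) = 11/6

    def test_correction_factor_is_preclamp_ratio(self):
        p = [1e-6, 2e-6, 3e-6, 4e-6, 1.7e-4] + list(np.linspace(0.5, 0.99, 73))
        adj, fac = adjust_bh(p)
        assert fac[4] == pytest.approx(78 / 5)  # 15.6
        assert adj[4] == pytest.approx(1.7e-4 * 15.6)

    def test_matches_independent_step_up_reference(self):
        """1000 random p-vectors against statsmodels' implementations."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m)
            for ours, method in ((adjust_bh, "fdr_bh"), (adjust_by, "fdr_by")):
                got, _ = ours(p)
                ref = multipletests(p, method=method)[1]
                np.testing.assert_allclose(got, ref, rtol=1e-12, atol=1e-15)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


def _planted_tables(rng, n_genes, depth, base, swap):
    tables = {}
    for i in range(n_genes):
        a = rng.multinomial(depth, base)
        b = rng.multinomial(depth, swap)
        counts = {f"i{j}": {"A": int(a[j]), "B": int(b[j])} for j in range(len(base))}
        tables[f"g{i:04d}"] = UsageTable.from_counts(f"g{i:04d}", counts)
    return tables


class TestFeatureUsage:
    def test_depth_threshold_boundary(self):
        t25 = UsageTable.from_counts("g", {"a": {"A": 13, "B": 13}, "b": {"A": 12, "B": 12}})
        t24 = UsageTable.from_counts("g", {"a": {"A": 12, "B": 13}, "b": {"A": 12, "B": 12}})
        (r25,) = feature_usage_test({"g": t25}, ("A", "B"))
        (r24,) = feature_usage_test({"g": t24}, ("A", "B"))
        assert r25.testable
        assert not r24.testable and r24.reason == "depth"

    def test_single_feature_untestable(self):
        t = UsageTable.from_counts("g", {"a": {"A": 30, "B": 30}})
        (r,) = feature_usage_test({"g": t}, ("A", "B"))
        assert not r.testable and r.reason == "single_feature"

    def test_tss_kind_aggregates_over_peaks(self):
        counts = {
            "g|T1|1-2|P1": {"A": 20, "B": 5},
            "g|T1|1-3|P1": {"A": 10, "B": 5},
            "g|T2|1-2|P1": {"A": 5, "B": 25},
        }
        t = UsageTable.from_counts("g", counts)
        (r,) = feature_usage_test({"g": t}, ("A", "B"), kind="TSS")
        assert r.testable
        # TSS-level table: T1 = (30, 10), T2 = (5, 25)
        assert r.effect == pytest.approx(30 / 35 - 10 / 35)

    def test_null_type_one_error_near_nominal(self):
        base = np.array([0.5, 0.2, 0.2, 0.1])
        rng = np.random.default_rng(5)
        tables = _planted_tables(rng, 1000, 100, base, base)
        res = feature_usage_test(tables, ("A", "B"))
        raw = np.array([r.raw_p for r in res if r.testable])
        assert 0.03 <= (raw < 0.05).mean() <= 0.07

    def test_power_and_effect_recovery_for_planted_swap(self):
        base = np.array([0.5, 0.2, 0.2, 0.1])
        swap = base[[1, 0, 2, 3]]  # true top-two DeltaPi = 0.3
        rng = np.random.default_rng(17)
        tables = _planted_tables(rng, 500, 100, base, swap)
        res = feature_usage_test(tables, ("A", "B"))
        sig = np.mean([r.significant for r in res])
        assert sig >= 0.8
        effects = np.abs([r.effect for r in res])
        se = 0.1  # approximate sampling SE of the top-two estimator at depth 100
        assert np.mean(np.abs(effects - 0.3) <= 3 * se) >= 0.95
        assert abs(effects.mean() - 0.3) < 0.1

    def test_power_monotone_in_depth(self):
        base = np.array([0.5, 0.2, 0.2, 0.1])
        swap = base[[1, 0, 2, 3]]
        powers = []
        for depth in (25, 50, 100, 200):
            rng = np.random.default_rng(100 + depth)
            tables = _planted_tables(rng, 300, depth, base, swap)
            res = feature_usage_test(tables, ("A", "B"))
            powers.append(np.mean([r.significant for r in res]))
        assert powers == sorted(powers)


class TestExonTests:
    def test_expected_count_eligibility_boundary(self):
        assert exon_test_eligible([[5, 5], [5, 5]])  # 10*10/20 = 5, boundary
        assert not exon_test_eligible([[1, 1], [1, 16]])  # ~0.21 < 5

    def _counts(self, rows):
        return pd.DataFrame(
            [
                {"exon_id": eid, "gene_id": "g", "group": grp,
                 "inclusion": inc, "exclusion": exc,
                 "terminal": False, "overlapping": False}
                for eid, grp, inc, exc in rows
            ]
        )

    def test_constitutive_exon_skipped(self):
        counts = self._counts([("e", "A", 95, 5), ("e", "B", 95, 5)])
        (r,) = exon_usage_test(counts, ("A", "B"))
        assert not r.testable and r.reason == "constitutive"

    def test_significant_switch_detected_with_by_correction(self):
        counts = self._counts(
            [("e1", "A", 81, 19), ("e1", "B", 22, 78),
             ("e2", "A", 50, 50), ("e2", "B", 50, 50)]
        )
        res = {r.feature_id: r for r in exon_usage_test(counts, ("A", "B"))}
        assert res["e1"].significant
        assert res["e1"].effect == pytest.approx(0.59)
        assert not res["e2"].significant
        # BY multiplies BH by c(m); adjusted must be >= BH-adjusted
        adj_bh, _ = adjust_bh([res["e1"].raw_p, res["e2"].raw_p])
        assert res["e1"].adjusted_p >= adj_bh[0]
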