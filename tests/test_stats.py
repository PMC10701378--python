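"""Assumption tests, omnibus branching, post hoc batteries, FDR and chi-square."""

import numpy as np
import pytest
from scipy import stats as sps

from hotwalk import (DegenerateDataError, ValidationError,
                     chi_square_categorical, dunn_pairwise, fdr_adjust,
                     normality_test, omnibus_compare, pearson_correlations,
                     variance_test)
from hotwalk.stats import PAIRS, compare_all_features

import pandas as pd


class TestNormality:
    def test_too_small_or_constant(self):
        with pytest.raises(DegenerateDataError):
            normality_test([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            normality_test([3.0, 3.0, 3.0, 3.0])

    def test_level_on_gaussian_samples(self):
        rng = np.random.default_rng(0)
        passes = sum(normality_test(rng.standard_normal(1000))[2]
                     for _ in range(100))
        assert passes >= 94

    def test_power_on_heavy_tails(self):
        rng = np.random.default_rng(1)
        fails = sum(not normality_test(rng.standard_t(df=2, size=1000))[2]
                    for _ in range(100))
        assert fails >= 90

    def test_tiny_sample_uses_simulated_null(self):
        stat, p, passed = normality_test([0.1, 0.5, 0.9])
        assert 0 <= p <= 1 and stat > 0


class TestVariance:
    def test_identical_groups(self):
        stat, p, ok = variance_test([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0) and ok

    def test_power_on_unequal_variances(self):
        rng = np.random.default_rng(2)
        rejects = sum(
            not variance_test([rng.normal(0, 1, 50), rng.normal(0, 5, 50)])[2]
            for _ in range(200))
        assert rejects >= 190

    def test_level_on_equal_variances(self):
        rng = np.random.default_rng(3)
        rejects = sum(
            not variance_test([rng.normal(0, 1, 20) for _ in range(3)])[2]
            for _ in range(2000))
        assert 0.03 <= rejects / 2000 <= 0.07

    def test_all_constant_degenerate(self):
        with pytest.raises(DegenerateDataError):
            variance_test([[1.0, 1.0], [1.0, 1.0]])


class TestOmnibus:
    def test_two_group_kruskal_wallis_reduction(self):
        """Hand-ranked KW: groups {1,2} vs {3,4} give H = 2.4."""
        res = omnibus_compare({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        assert res.omnibus_method == "Kruskal-Wallis"
        assert res.statistic == pytest.approx(2.4)

    def test_identical_groups_null(self):
        g = [1.0, 1.0, 1.0, 1.0]
        res = omnibus_compare({"AD": g, "aMCI": g, "NC": g})
        assert res.p_value == pytest.approx(1.0)
        assert all(pr.p_adjusted == 0.999 for pr in res.pairwise.values())

    def test_branch_is_function_of_assumptions(self):
        rng = np.random.default_rng(4)
        norm_groups = {g: rng.normal(0, 1, 40) for g in ("AD", "aMCI", "NC")}
        res = omnibus_compare(norm_groups)
        if all(res.normality.values()) and res.variance_homogeneous:
            assert res.omnibus_method == "one-way ANOVA"
        skewed = {g: rng.exponential(1, 40) ** 3 for g in ("AD", "aMCI", "NC")}
        res2 = omnibus_compare(skewed)
        assert not all(res2.normality.values())
        assert res2.omnibus_method == "Kruskal-Wallis"
        assert all(pr.method.startswith("Dunn") for pr in res2.pairwise.values())

    def test_detects_separated_groups(self):
        rng = np.random.default_rng(5)
        groups = {"AD": rng.normal(10, 1, 15), "aMCI": rng.normal(5, 1, 15),
                  "NC": rng.normal(0, 1, 15)}
        res = omnibus_compare(groups)
        assert res.p_value < 1e-6
        assert res.pairwise[("AD", "NC")].p_adjusted < 1e-4


class TestDunn:
    # fixture: 3 groups x 4 values with a tie across groups
    GROUPS = {"A": [1.0, 3.0, 5.0, 7.0],
              "B": [2.0, 4.0, 6.0, 8.0],
              "C": [5.0, 9.0, 10.0, 11.0]}

    @staticmethod
    def _hand_dunn(groups):
        """Independent computation: explicit sorting-based ranks, tie term,
        pooled variance, Bonferroni cap."""
        import itertools, math
        pooled = [(v, g) for g, vs in groups.items() for v in vs]
        vals = sorted(v for v, _ in pooled)
        ranks = {}
        i = 0
        while i < len(vals):
            j = i
            while j < len(vals) and vals[j] == vals[i]:
                j += 1
            for k in range(i, j):
                ranks.setdefault(vals[i], (i + j + 1) / 2.0)
            i = j
        n = len(pooled)
        rbar = {g: np.mean([ranks[v] for v in vs]) for g, vs in groups.items()}
        ties = {}
        for v in vals:
            ties[v] = ties.get(v, 0) + 1
        T = sum(t ** 3 - t for t in ties.values())
        base = n * (n + 1) / 12.0 - T / (12.0 * (n - 1))
        out = {}
        for a, b in itertools.combinations(groups, 2):
            se = math.sqrt(base * (1 / len(groups[a]) + 1 / len(groups[b])))
            z = (rbar[a] - rbar[b]) / se
            p = 2 * sps.norm.sf(abs(z))
            out[(a, b)] = (z, p, min(p * 3, 0.999))
        return out

    def test_matches_hand_computation(self):
        got = dunn_pairwise(self.GROUPS)
        expect = self._hand_dunn(self.GROUPS)
        for pair, (z, p, padj) in expect.items():
            assert got[pair].statistic == pytest.approx(z)
            assert got[pair].p_raw == pytest.approx(p)
            assert got[pair].p_adjusted == pytest.approx(padj)

    def test_null_pair_capped(self):
        groups = {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0],
                  "C": [10.0, 11.0, 12.0]}
        res = dunn_pairwise(groups)
        assert res[("A", "B")].p_adjusted == 0.999

    def test_adjusted_at_least_raw(self):
        res = dunn_pairwise(self.GROUPS)
        for pr in res.values():
            assert pr.p_adjusted >= min(pr.p_raw, 0.999)


class TestChiSquare:
    def test_balanced_table_is_null(self):
        stat, p, _ = chi_square_categorical([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_sex_by_group_matches_hand_computation(self):
        table = np.array([[9, 8], [10, 4], [11, 4]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = float(((table - expected) ** 2 / expected).sum())
        stat, p, pairwise = chi_square_categorical(table)
        assert stat == pytest.approx(hand)
        assert set(pairwise) == {(0, 1), (0, 2), (1, 2)}
        assert all(0 < v <= 0.999 for v in pairwise.values())

    def test_scaling_property(self):
        t = [[9, 8], [10, 4]]
        s1, _, _ = chi_square_categorical(t)
        s2, _, _ = chi_square_categorical(np.array(t) * 2)
        assert s2 == pytest.approx(2 * s1)

    def test_zero_margin(self):
        with pytest.raises(DegenerateDataError):
            chi_square_categorical([[0, 0], [3, 4]])


class TestPearson:
    def _tables(self, x, y):
        ids = [f"P{i}" for i in range(len(x))]
        return (pd.DataFrame({"participant_id": ids, "score": x}),
                pd.DataFrame({"participant_id": ids, "cov": y}))

    def test_perfect_linear(self):
        x = np.arange(10.0)
        (r,) = pearson_correlations(*self._tables(x, 2 * x + 1))
        assert r.r == pytest.approx(1.0)
        (r,) = pearson_correlations(*self._tables(x, -x))
        assert r.r == pytest.approx(-1.0)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(6)
        rejects = 0
        for _ in range(2000):
            x, y = rng.standard_normal((2, 50))
            (res,) = pearson_correlations(*self._tables(x, y))
            rejects += res.p < 0.05
        assert 0.03 <= rejects / 2000 <= 0.07

    def test_constant_variable_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_correlations(*self._tables(np.ones(10), np.arange(10.0)))


class TestFdr:
    def test_hand_step_up(self):
        # min over j >= i of p_(j) * m / j
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])
        assert fdr_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(fdr_adjust([0.03, 0.03, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_formula_on_random_inputs(self):
        rng = np.random.default_rng(7)
        p = rng.random(25)
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            hand[order[rank]] = running
        assert np.allclose(fdr_adjust(p), hand)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.random(12)
        perm = rng.permutation(12)
        assert np.allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]))

    def test_range_validation(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])


class TestCompareAllFeatures:
    def _table(self, seed=9, shift=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("AD", "aMCI", "NC"):
            off = {"AD": 2 * shift, "aMCI": shift, "NC": 0.0}[g]
            for _ in range(15):
                rows.append({"group": g,
                             "n_outliers": rng.poisson(20 + 40 * off),
                             "mean_outlier_run_distance_m": rng.gamma(2, 0.02 + 0.01 * off),
                             "n_stay_points": rng.poisson(14 + 8 * off)})
        return pd.DataFrame(rows)

    def test_report_shape_and_fdr_family(self):
        report, results = compare_all_features(self._table(shift=1.0))
        assert len(report) == 3
        assert {"mean_AD", "sd_NC", "omnibus_p", "p_AD_vs_NC"} <= set(report.columns)
        for feat, res in results.items():
            for pr in res.pairwise.values():
                assert pr.method.endswith("FDR")
                assert pr.p_adjusted <= 0.999

    def test_strong_effects_detected(self):
        report, _ = compare_all_features(self._table(shift=1.0))
        row = report.set_index("feature").loc["n_stay_points"]
        assert row["p_AD_vs_NC"] < 0.05

    def test_null_mostly_clean(self):
        report, _ = compare_all_features(self._table(seed=11, shift=0.0))
        assert (report[[f"p_{a}_vs_{b}" for a, b in PAIRS]].to_numpy()
                < 0.01).sum() == 0
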