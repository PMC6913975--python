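"""Rank tests, core-codon scan, two-way ANOVA and Holm-Sidak adjustment."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cubkit.codons import BACTERIAL_CODE, CodonCountTable
from cubkit.simulate import UsageModel, generate_gene
from cubkit.codons import count_codons
from cubkit.stats import (
    core_codon_scan,
    holm_sidak,
    kruskal_wallis,
    mann_whitney_u,
    two_way_anova,
)


def mw_u_pair_counting(a, b):
    """Oracle: U by direct pair comparison (ties count half)."""
    u1 = sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )
    return min(u1, len(a) * len(b) - u1)


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney_u([1, 2], [3, 4]).statistic == 0.0

    def test_midrank_hand_example(self):
        # pooled {1,1,1,2}: midranks (2,2),(2,4); R1=4, U1=1
        res = mann_whitney_u([1, 1], [1, 2])
        assert res.statistic == 1.0

    def test_statistic_matches_pair_counting(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(1, 15))
            n2 = int(rng.integers(1, 15))
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            assert mann_whitney_u(a, b).statistic == pytest.approx(
                mw_u_pair_counting(a, b), abs=1e-9
            )

    def test_large_sample_p_matches_scipy_asymptotic(self, rng):
        for _ in range(100):
            a = rng.integers(0, 10, 15).astype(float)
            b = rng.integers(0, 10, 18).astype(float)
            mine = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            assert mine.p_value == pytest.approx(float(ref.pvalue), abs=1e-8)

    def test_monotone_transform_invariance(self, rng):
        for _ in range(30):
            a = rng.normal(size=8)
            b = rng.normal(size=9)
            r1 = mann_whitney_u(a, b)
            r2 = mann_whitney_u(np.exp(a), np.exp(b))
            assert r1.statistic == pytest.approx(r2.statistic)
            assert r1.p_value == pytest.approx(r2.p_value)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_example(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        # H = 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7
        assert res.statistic == pytest.approx(12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21)
        assert res.statistic == pytest.approx(4.5714285, abs=1e-6)
        assert res.df == 2

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            groups = [rng.integers(0, 5, int(rng.integers(2, 10))).astype(float)
                      for _ in range(k)]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            mine = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert mine.statistic == pytest.approx(float(ref.statistic), abs=1e-8)
            assert mine.p_value == pytest.approx(float(ref.pvalue), abs=1e-8)

    def test_two_groups_equals_mw_z_squared(self, rng):
        # tie-corrected H on 2 groups equals the (tie-corrected, no-cc) MW z^2
        for _ in range(50):
            a = rng.integers(0, 8, 12).astype(float)
            b = rng.integers(0, 8, 14).astype(float)
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                continue
            h = kruskal_wallis([a, b]).statistic
            ref = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            z = sps.norm.isf(float(ref.pvalue) / 2)
            assert h == pytest.approx(z * z, abs=1e-6)


class TestCoreCodonScan:
    def _cohort(self, rng, model, n_species=40, length=300):
        tables = []
        for i in range(n_species):
            g = generate_gene(length, model, rng, seq_id=f"sp{i}")
            tables.append(count_codons(g))
        return tables

    def test_planted_preference_detected(self, rng):
        model = UsageModel(
            mode="selected", alpha=None, preferred={"L": "CTG"},
            preferred_weight=5.0,
        )
        tables = self._cohort(rng, model, n_species=100)
        out = core_codon_scan(tables)
        leu = out[out.amino_acid == "L"].iloc[0]
        assert leu["p_value"] < 0.001 and leu["significant"]

    def test_covers_18_families(self, rng):
        tables = self._cohort(rng, UsageModel(mode="selected", alpha=None),
                              n_species=10)
        out = core_codon_scan(tables)
        assert len(out) == 18
        assert set(out[out.family_size == 2]["test"]) == {"mann_whitney"}
        assert set(out[out.family_size > 2]["test"]) == {"kruskal_wallis"}
        assert "M" not in set(out.amino_acid) and "W" not in set(out.amino_acid)

    def test_frequency_mode_scales(self, rng):
        tables = self._cohort(rng, UsageModel(mode="selected", alpha=None),
                              n_species=10)
        out = core_codon_scan(tables, mode="frequencies")
        assert len(out) == 18

    def test_needs_three_species(self, rng):
        with pytest.raises(ValueError):
            core_codon_scan(self._cohort(rng, UsageModel(), n_species=2))


def balanced_anova_oracle(cells):
    """Closed-form cell-mean decomposition for a balanced a x b design.

    ``cells[(i, j)]`` is the list of replicates in cell (i, j).
    Returns (SS_A, SS_B, SS_AB, SS_res).
    """
    a_levels = sorted({i for i, _ in cells})
    b_levels = sorted({j for _, j in cells})
    r = len(next(iter(cells.values())))
    grand = np.mean([x for v in cells.values() for x in v])
    mean_a = {i: np.mean([x for j in b_levels for x in cells[(i, j)]])
              for i in a_levels}
    mean_b = {j: np.mean([x for i in a_levels for x in cells[(i, j)]])
              for j in b_levels}
    mean_ab = {key: np.mean(v) for key, v in cells.items()}
    ss_a = r * len(b_levels) * sum((mean_a[i] - grand) ** 2 for i in a_levels)
    ss_b = r * len(a_levels) * sum((mean_b[j] - grand) ** 2 for j in b_levels)
    ss_ab = r * sum(
        (mean_ab[(i, j)] - mean_a[i] - mean_b[j] + grand) ** 2
        for i in a_levels for j in b_levels
    )
    ss_res = sum(
        (x - mean_ab[key]) ** 2 for key, v in cells.items() for x in v
    )
    return ss_a, ss_b, ss_ab, ss_res


class TestTwoWayAnova:
    def test_hand_decomposition(self):
        vals = [1, 3, 1, 3, 5, 7, 5, 7]
        A = ["a1"] * 4 + ["a2"] * 4
        B = ["b1", "b1", "b2", "b2"] * 2
        res = two_way_anova(vals, A, B)
        assert res.terms.loc["factor_A", "sum_of_squares"] == pytest.approx(32.0)
        assert res.terms.loc["factor_B", "sum_of_squares"] == pytest.approx(0.0, abs=1e-9)
        assert res.terms.loc["interaction", "sum_of_squares"] == pytest.approx(0.0, abs=1e-9)
        assert res.terms.loc["residual", "sum_of_squares"] == pytest.approx(8.0)
        assert res.terms.loc["factor_A", "F"] == pytest.approx(16.0)

    def test_constant_response(self):
        res = two_way_anova([2.0] * 8, ["a", "a", "b", "b"] * 2,
                            ["x", "y"] * 4)
        for term in ("factor_A", "factor_B"):
            assert res.terms.loc[term, "sum_of_squares"] == pytest.approx(0, abs=1e-9)
            assert res.terms.loc[term, "p_value"] == 1.0

    def test_balanced_matches_cell_mean_oracle(self, rng):
        for _ in range(50):
            a_n = int(rng.integers(2, 4))
            b_n = int(rng.integers(2, 4))
            r = int(rng.integers(2, 5))
            cells = {
                (i, j): rng.normal(size=r).tolist()
                for i in range(a_n) for j in range(b_n)
            }
            vals, A, B = [], [], []
            for (i, j), v in cells.items():
                vals += v
                A += [f"a{i}"] * r
                B += [f"b{j}"] * r
            res = two_way_anova(vals, A, B)
            ss = balanced_anova_oracle(cells)
            assert res.terms.loc["factor_A", "sum_of_squares"] == pytest.approx(ss[0], abs=1e-9)
            assert res.terms.loc["factor_B", "sum_of_squares"] == pytest.approx(ss[1], abs=1e-9)
            assert res.terms.loc["interaction", "sum_of_squares"] == pytest.approx(ss[2], abs=1e-9)
            assert res.terms.loc["residual", "sum_of_squares"] == pytest.approx(ss[3], abs=1e-9)

    def test_df_sum_to_n_minus_1(self, rng):
        vals = rng.normal(size=24)
        A = ["a", "b"] * 12
        B = ["x"] * 8 + ["y"] * 8 + ["z"] * 8
        res = two_way_anova(vals, list(A), B)
        assert res.terms["df"].sum() == pytest.approx(23)

    def test_empty_cell_drops_interaction(self, rng):
        vals = rng.normal(size=9).tolist()
        A = ["a"] * 3 + ["b"] * 6
        B = ["x", "x", "x", "x", "x", "x", "y", "y", "y"]  # cell (a, y) empty
        res = two_way_anova(vals, A, B)
        assert res.interaction_dropped
        assert "interaction" not in res.terms.index

    def test_posthoc_present_and_adjusted(self, rng):
        vals = rng.normal(size=30)
        A = (["a", "b"] * 15)
        B = ["x"] * 10 + ["y"] * 10 + ["z"] * 10
        res = two_way_anova(vals, list(A), B)
        labels = [c for c, _ in res.posthoc]
        assert any("factor_B" in l for l in labels)
        assert all(0 <= p <= 1 for _, p in res.posthoc)


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert holm_sidak([0.03]) == pytest.approx([0.03])

    def test_two_p_hand_example(self):
        out = holm_sidak([0.01, 0.04])
        assert out[0] == pytest.approx(1 - 0.99**2)
        assert out[1] == pytest.approx(0.04)

    def test_all_zero(self):
        assert holm_sidak([0.0, 0.0, 0.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_pointwise_dominates_input_and_monotone(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 12)))
            adj = np.array(holm_sidak(p))
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1.0)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=8)
            mine = holm_sidak(p)
            ref = multipletests(p, method="holm-sidak")[1]
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])
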