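"""Normalization, filtering, mid-parent synthesis, and the exact test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, binomtest

from hetmir import (
    DEThresholds,
    bh_adjust,
    binomial_exact_test,
    cpm,
    de_contrast,
    filter_low_expression,
    synthesize_midparent,
    with_midparent,
)
from hetmir.diffexpr import _minlike_two_sided


def minlike_bruteforce(k1: int, n1: int, k2: int, n2: int) -> float:
    """Independent oracle: enumerate the conditional binomial outright."""
    n = k1 + k2
    if n == 0:
        return 1.0
    p0 = n1 / (n1 + n2)
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k1] * (1 + 1e-7)].sum()))


class TestCPM:
    def test_arithmetic(self, tiny):
        counts, _ = tiny
        norm = cpm(counts)
        # 100 / 1000 * 1e6
        assert norm.loc["mir-a", "P1_1"] == pytest.approx(1e5)
        assert np.allclose(norm.sum(axis=0), 1e6)

    def test_seven_in_350k(self):
        counts = pd.DataFrame({"s1": [7, 349_993]}, index=["m1", "m2"])
        assert cpm(counts).loc["m1", "s1"] == pytest.approx(20.0)

    def test_zero_library_named(self, tiny):
        counts, _ = tiny
        counts = counts.copy()
        counts["P1_1"] = 0
        with pytest.raises(ValueError, match="P1_1"):
            cpm(counts)

    def test_single_nonzero_cell_is_million(self):
        counts = pd.DataFrame({"s1": [50, 0, 0]}, index=["m1", "m2", "m3"])
        assert cpm(counts).loc["m1", "s1"] == pytest.approx(1e6)


class TestLowExpressionFilter:
    @pytest.mark.parametrize(
        "row, kept",
        [
            (np.full(16, 9.9), False),   # below threshold everywhere
            ([12.0] + [0.0] * 15, True),  # one library suffices
            (np.full(16, 10.0), True),    # boundary: strict '<' drops, so 10.0 kept
        ],
    )
    def test_rule(self, row, kept):
        norm = pd.DataFrame({f"s{i}": [v] for i, v in enumerate(row)}, index=["m"])
        kept_ids, dropped_ids = filter_low_expression(norm, 10.0)
        assert ("m" in kept_ids) is kept
        assert ("m" in dropped_ids) is (not kept)

    def test_partition(self, tiny):
        counts, _ = tiny
        norm = cpm(counts)
        kept, dropped = filter_low_expression(norm)
        assert sorted(kept + dropped) == sorted(norm.index)


class TestMidparent:
    def test_formula_and_symmetry(self, tiny):
        counts, samples = tiny
        norm = cpm(counts)
        a = synthesize_midparent(norm, samples)
        assert list(a.columns) == ["A_1", "A_2"]
        expected = (norm["P1_1"] + norm["P2_1"]) / 2
        assert np.allclose(a["A_1"], expected)
        # swapping parent labels leaves A unchanged
        swapped = samples.copy()
        swapped["genotype"] = swapped["genotype"].map({"P1": "P2", "P2": "P1"})
        assert np.allclose(synthesize_midparent(norm, swapped).values, a.values)

    def test_identical_parents(self, tiny):
        counts, samples = tiny
        counts = counts.copy()
        counts["P2_1"] = counts["P1_1"]
        counts["P2_2"] = counts["P1_2"]
        norm = cpm(counts)
        a = synthesize_midparent(norm, samples)
        assert np.allclose(a["A_1"], norm["P1_1"])

    def test_missing_parent_raises(self, tiny):
        counts, samples = tiny
        only_p1 = samples[samples["genotype"] == "P1"]
        with pytest.raises(ValueError, match="P2"):
            synthesize_midparent(cpm(counts), only_p1)

    def test_pseudocounts_at_mean_library(self, tiny):
        counts, samples = tiny
        aug_counts, aug_samples, totals = with_midparent(counts, samples)
        assert {"A_1", "A_2"} <= set(aug_counts.columns)
        mean_lib = int(round(counts.sum(axis=0).mean()))
        assert (totals[["A_1", "A_2"]] == mean_lib).all()
        # pseudo-counts round-trip to the A CPM profile at that depth
        a = synthesize_midparent(cpm(counts), samples)
        back = aug_counts["A_1"] / mean_lib * 1e6
        assert np.allclose(back, a["A_1"], atol=1e6 / mean_lib)


class TestBinomialExactTest:
    @pytest.mark.parametrize(
        "k1, k2, expected",
        [
            (5, 5, 1.0),                  # observed value is the mode
            (10, 0, 2 * 0.5**10),         # both extreme tails
            (3, 1, 10 / 16),              # enumerated Binomial(4, 1/2)
        ],
    )
    def test_equal_libraries_examples(self, k1, k2, expected):
        assert binomial_exact_test(k1, 1000, k2, 1000) == pytest.approx(expected)

    def test_zero_total_convention(self):
        assert binomial_exact_test(0, 100, 0, 100) == 1.0

    def test_matches_scipy_binomtest(self):
        # independent library cross-check on unequal totals
        for k1, n1, k2, n2 in [(7, 1000, 30, 3000), (0, 500, 12, 700), (40, 900, 13, 1100)]:
            ours = binomial_exact_test(k1, n1, k2, n2)
            ref = binomtest(k1, k1 + k2, n1 / (n1 + n2)).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    @given(
        k1=st.integers(0, 60),
        k2=st.integers(0, 60),
        ratio=st.sampled_from([1, 2, 10]),
    )
    @settings(max_examples=150, deadline=None)
    def test_bruteforce_property(self, k1, k2, ratio):
        n1, n2 = 10_000, 10_000 * ratio
        assert binomial_exact_test(k1, n1, k2, n2) == pytest.approx(
            minlike_bruteforce(k1, n1, k2, n2), rel=1e-9
        )

    @given(k1=st.integers(0, 80), k2=st.integers(0, 80))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, k1, k2):
        p_ab = binomial_exact_test(k1, 1000, k2, 3000)
        p_ba = binomial_exact_test(k2, 3000, k1, 1000)
        assert p_ab == pytest.approx(p_ba, rel=1e-9)

    def test_large_total_branch_agrees_with_enumeration(self):
        # the binary-search tail method vs direct enumeration at the
        # 10,000 crossover, across a grid of imbalances
        n = 10_000
        for p0 in (0.5, 1 / 3, 1 / 11, 0.9):
            pmf = binom.pmf(np.arange(n + 1), n, p0)
            for k in (0, 17, 4000, 5000, 9000, n):
                enum = float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()))
                fast = _minlike_two_sided(k, n, p0)
                assert fast == pytest.approx(enum, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_exact_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            binomial_exact_test(11, 10, 0, 10)


class TestBHAdjust:
    def naive(self, p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = np.empty(m)
        ps = p[order]
        for i in range(m):
            q_sorted[i] = min(1.0, (ps[i:] * m / np.arange(i + 1, m + 1)).min())
        q = np.empty(m)
        q[order] = q_sorted
        return q

    def test_examples(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_naive_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        g = np.random.default_rng(7)
        for _ in range(25):
            p = g.random(int(g.integers(1, 200)))
            q = bh_adjust(p)
            assert np.allclose(q, self.naive(p))
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_rejects_bad_pvalues(self):
        for bad in ([-0.1], [1.2], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_q_dominates_p_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestDeContrast:
    def test_identical_groups_all_ns(self, tiny):
        counts, samples = tiny
        counts = counts.copy()
        counts["P2_1"], counts["P2_2"] = counts["P1_1"], counts["P1_2"]
        res = de_contrast(counts, samples, "P1", "P2")
        assert (res["status"] == "ns").all()
        assert np.allclose(res["log2fc"], 0.0)

    def test_reverse_contrast_mirrors(self, tiny):
        counts, samples = tiny
        fwd = de_contrast(counts, samples, "P1", "P2")
        rev = de_contrast(counts, samples, "P2", "P1")
        assert np.allclose(fwd["p"], rev["p"])
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert list(fwd["status"].map(swap)) == list(rev["status"])

    def test_fold_change_gate_is_conjunctive(self):
        # huge counts: tiny p, but log2fc 0.8 < 1 stays ns
        counts = pd.DataFrame(
            {"g1": [574_349, 1_000_000], "g2": [330_000, 1_000_000]},
            index=["m-gate", "m-ref"],
        )
        samples = pd.DataFrame(
            {"sample_id": ["g1", "g2"], "genotype": ["P1", "P2"], "replicate": [1, 1]}
        )
        res = de_contrast(counts, samples, "P1", "P2").set_index("mirna_id")
        row = res.loc["m-gate"]
        assert row["q"] < 0.05 and abs(row["log2fc"]) < 1
        assert row["status"] == "ns"

    def test_unknown_group(self, tiny):
        counts, samples = tiny
        with pytest.raises(ValueError, match="unknown group"):
            de_contrast(counts, samples, "P1", "H99")

    def test_status_matches_gates(self, recovery_run):
        for table in recovery_run["tables"].values():
            sig = (table["q"] < 0.05) & (table["log2fc"].abs() >= 1)
            assert ((table["status"] != "ns") == sig).all()
            up = table["status"] == "up"
            assert (table.loc[up, "log2fc"] > 0).all()
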