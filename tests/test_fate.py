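import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace.fate import (
    BALANCED,
    UNTESTED,
    bh_adjust,
    clone_fate_bias,
    fate_bias_test_table,
    fate_mapping,
    fisher_exact_one_sided,
    summarize_fate_bias,
)
from clonetrace.io import CloneMatrix

from conftest import random_clone_matrix


def fisher_oracle(a, b, c, d):
    """Exact upper-tail hypergeometric probability via Fraction enumeration."""
    n_total, big_k, n = a + b + c + d, a + c, a + b
    total = math.comb(n_total, n)
    num = sum(
        math.comb(big_k, k) * math.comb(n_total - big_k, n - k)
        for k in range(a, min(n, big_k) + 1)
    )
    return Fraction(num, total)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((3, 0, 0, 3), Fraction(1, 20)),  # 0.05
            ((2, 2, 2, 2), Fraction(53, 70)),
            ((10, 0, 0, 10), Fraction(1, math.comb(20, 10))),
        ],
    )
    def test_anchor_tables(self, table, expected):
        _, p = fisher_exact_one_sided(*table)
        assert p == pytest.approx(float(expected), rel=1e-12)

    def test_a_zero_gives_p_one(self):
        _, p = fisher_exact_one_sided(0, 5, 3, 2)
        assert p == 1.0

    @pytest.mark.parametrize(
        "table,expected_or",
        [((2, 2, 2, 2), 1.0), ((3, 0, 0, 3), math.inf), ((1, 1, 1, 1), 1.0)],
    )
    def test_odds_ratio_conventions(self, table, expected_or):
        odds, _ = fisher_exact_one_sided(*table)
        assert odds == expected_or

    def test_zero_numerator_odds_ratio(self):
        odds, _ = fisher_exact_one_sided(0, 3, 2, 5)
        assert odds == 0.0

    def test_all_zero_table_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided(0, 0, 0, 0)

    def test_empty_clone_row_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided(0, 0, 3, 4)

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or a + b + c + d == 0:
            return
        _, p = fisher_exact_one_sided(a, b, c, d)
        assert p == pytest.approx(float(fisher_oracle(a, b, c, d)), rel=1e-12)

    def test_matches_scipy_hypergeom_tail(self, rng):
        from scipy.stats import hypergeom

        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b == 0:
                continue
            _, p = fisher_exact_one_sided(a, b, c, d)
            expected = hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)
            assert p == pytest.approx(expected, rel=1e-9)


class TestBhAdjust:
    def test_hand_worked_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_fixed_points(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 50)))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_permutation_invariant_and_monotone(self, p_list):
        p = np.array(p_list)
        adj = bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestFateMapping:
    def test_normalizes_rows(self):
        m = CloneMatrix(["c1", "c2"], ["A", "B", "C"], np.array([[2, 3, 5], [4, 0, 0]]))
        fm = fate_mapping(m)
        np.testing.assert_allclose(fm.values[0], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(fm.values[1], [1.0, 0.0, 0.0])

    def test_row_sums_one_on_random_matrices(self, rng):
        for _ in range(50):
            m = random_clone_matrix(rng, n_clones=int(rng.integers(3, 40)))
            fm = fate_mapping(m)
            np.testing.assert_allclose(fm.values.sum(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance(self, rng):
        m = random_clone_matrix(rng, n_clones=5)
        scaled = CloneMatrix(
            m.clone_ids, m.column_labels, m.counts * np.array([1, 3, 1, 7, 2])[:, None]
        )
        np.testing.assert_allclose(
            fate_mapping(scaled).values, fate_mapping(m).values, atol=1e-12
        )


class TestCloneFateBias:
    def test_two_disjoint_clones_both_biased(self):
        m = CloneMatrix(["c1", "c2"], ["T1", "T2"], np.array([[10, 0], [0, 10]]))
        calls = {c.clone_id: c for c in clone_fate_bias(m)}
        assert calls["c1"].label == "T1 biased"
        assert calls["c2"].label == "T2 biased"
        assert calls["c1"].p_value == pytest.approx(1 / math.comb(20, 10), rel=1e-9)
        assert (calls["c1"].a, calls["c1"].b, calls["c1"].c, calls["c1"].d) == (
            10, 0, 0, 10,
        )

    def test_background_matched_clone_is_balanced(self):
        # clone c4 distributed exactly proportional to the others' pooled counts
        m = CloneMatrix(
            ["c1", "c2", "c3", "c4"],
            ["A", "B", "C"],
            np.array([[10, 0, 10], [0, 10, 10], [0, 10, 10], [1, 2, 3]]),
        )
        tests = fate_bias_test_table(m)
        c4 = tests[tests["clone_id"] == "c4"]
        assert (c4["p_value"] >= 0.5).all()
        calls = {c.clone_id: c for c in clone_fate_bias(m)}
        assert calls["c4"].label == BALANCED

    def test_alpha_zero_all_balanced(self, rng):
        m = random_clone_matrix(rng, n_clones=10)
        calls = clone_fate_bias(m, alpha=0.0)
        assert all(c.label in (BALANCED, UNTESTED) for c in calls)

    def test_size_one_clones_untested(self):
        m = CloneMatrix(["c1", "c2"], ["T1", "T2"], np.array([[1, 0], [5, 5]]))
        calls = {c.clone_id: c for c in clone_fate_bias(m)}
        assert calls["c1"].label == UNTESTED

    def test_named_target_groupings(self):
        m = CloneMatrix(
            ["c1", "c2", "c3"],
            ["T", "B", "Ery"],
            np.array([[6, 6, 0], [0, 1, 11], [1, 1, 10]]),
        )
        calls = clone_fate_bias(m, targets={"lymphoid": ["T", "B"], "erythroid": ["Ery"]})
        by_id = {c.clone_id: c for c in calls}
        assert by_id["c1"].label == "lymphoid biased"
        assert by_id["c1"].a == 12

    def test_unknown_target_label_errors(self, small_matrix):
        with pytest.raises(ValueError, match="unknown"):
            clone_fate_bias(small_matrix, targets={"x": ["nope"]})

    def test_table_invariants(self, rng):
        m = random_clone_matrix(rng, n_clones=15, n_types=3)
        tests = fate_bias_test_table(m)
        sizes = dict(zip(m.clone_ids, m.counts.sum(axis=1)))
        totals = dict(zip(m.column_labels, m.counts.sum(axis=0)))
        for row in tests.itertuples():
            assert row.a + row.b == sizes[row.clone_id]
            assert row.a + row.c == totals[row.target]
            assert row.a + row.b + row.c + row.d == m.total


class TestSummarize:
    def _call(self, clone, label, size=4):
        from clonetrace.fate import FateBiasCall

        return FateBiasCall(clone, "", size, 0, 0, 0, 1.0, 0.5, 0.5, label)

    def test_fraction_counting(self):
        calls = [
            self._call("c1", "A biased"),
            self._call("c2", "A biased"),
            self._call("c3", BALANCED),
            self._call("c4", "B biased"),
        ]
        df = summarize_fate_bias(calls).set_index("label")
        assert df.loc["A biased", "fraction"] == pytest.approx(0.5)
        assert df.loc["B biased", "fraction"] == pytest.approx(0.25)
        assert df["fraction"].sum() == pytest.approx(1.0)
        assert df["n_clones"].sum() == 4

    def test_all_balanced_single_row(self):
        df = summarize_fate_bias([self._call("c1", BALANCED)])
        assert df["fraction"].tolist() == [1.0]

    def test_cell_weighting(self):
        calls = [self._call("c1", "A biased", size=30), self._call("c2", BALANCED, size=10)]
        df = summarize_fate_bias(calls, weight="cell").set_index("label")
        assert df.loc["A biased", "fraction"] == pytest.approx(0.75)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_fate_bias([])

    def test_planted_fraction_recovered_within_binomial_interval(self):
        from clonetrace.simulate import benchmark_config, simulate_experiment

        exp = simulate_experiment(
            benchmark_config(11), include_counts=False, include_motifs=False
        )
        calls = clone_fate_bias(exp.clone_matrix)
        tested = [c for c in calls if c.label != UNTESTED]
        frac_biased = np.mean([c.label != BALANCED for c in tested])
        n = len(tested)
        half_width = 1.96 * math.sqrt(0.3 * 0.7 / n)
        assert abs(frac_biased - 0.3) <= half_width + 0.02
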