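import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

from clonetrace.differential import (
    _wilcoxon_exact_p,
    _wilcoxon_normal_p,
    fate_bias_diff,
    nb_test,
    volcano_table,
    wilcoxon_test,
    DiffResult,
    nearest_tss_genes,
)
from clonetrace.fate import FateBiasCall
from clonetrace.io import CellRecord, CountMatrix, PeakRegion


def wilcoxon_enumeration_oracle(a, b):
    """Independent brute force: distribution of the rank sum over labelings."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n, n_a = len(pooled), len(a)
    w_obs = ranks[:n_a].sum()
    e_w = n_a * (n + 1) / 2
    dev = abs(w_obs - e_w)
    hits = sum(
        1
        for idx in combinations(range(n), n_a)
        if abs(sum(ranks[i] for i in idx) - e_w) >= dev - 1e-9
    )
    return hits / math.comb(n, n_a)


class TestNbTest:
    def test_identical_groups_zero_lfc(self, rng):
        y = rng.poisson(5, 30)
        lfc, p = nb_test(y, y.copy())
        assert lfc == 0.0
        assert p > 0.5

    def test_all_zero_feature_reported_not_significant(self):
        lfc, p = nb_test([0] * 5, [0] * 5)
        assert (lfc, p) == (0.0, 1.0)

    def test_group_swap_negates_lfc_keeps_p(self, rng):
        ya = rng.poisson(8, 40)
        yb = rng.poisson(4, 40)
        lfc_ab, p_ab = nb_test(ya, yb)
        lfc_ba, p_ba = nb_test(yb, ya)
        assert lfc_ab == pytest.approx(-lfc_ba, abs=1e-9)
        assert p_ab == pytest.approx(p_ba, rel=1e-3)

    def test_poisson_limit_agrees_with_poisson_glm(self, rng):
        import statsmodels.api as sm

        for _ in range(5):
            ya = rng.poisson(6.0, 100)
            yb = rng.poisson(4.5, 100)
            _, p = nb_test(ya, yb)
            y = np.concatenate([yb, ya])
            x = sm.add_constant(np.concatenate([np.zeros(100), np.ones(100)]))
            full = sm.GLM(y, x, family=sm.families.Poisson()).fit()
            null = sm.GLM(y, np.ones((200, 1)), family=sm.families.Poisson()).fit()
            stat = 2 * (full.llf - null.llf)
            from scipy.stats import chi2

            p_pois = chi2.sf(stat, 1)
            # NB LRT approaches the Poisson GLM LRT as dispersion -> 0
            assert p == pytest.approx(p_pois, rel=0.10, abs=5e-4)

    def test_planted_fold_change_detected(self, rng):
        r = 1 / 0.5
        hits = 0
        for _ in range(40):
            ya = rng.poisson(rng.gamma(r, 20.0 / r, 100))
            yb = rng.poisson(rng.gamma(r, 5.0 / r, 100))
            lfc, p = nb_test(ya, yb)
            hits += p < 0.05 and abs(lfc) > 0.5
        assert hits >= 38

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError):
            nb_test([1, 2], [3, 4, 5])


class TestWilcoxonTest:
    def test_exact_anchor_one_third(self):
        _, p = wilcoxon_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        lfc, p = wilcoxon_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0
        assert lfc == 0.0

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(200):
            n_a = int(rng.integers(1, 6))
            n_b = int(rng.integers(1, 11 - n_a))
            a = rng.integers(0, 5, n_a).astype(float)
            b = rng.integers(0, 5, n_b).astype(float)
            assert _wilcoxon_exact_p(a, b) == pytest.approx(
                wilcoxon_enumeration_oracle(a, b)
            )

    def test_normal_approximation_tracks_exact_at_boundary(self, rng):
        # at the exact/asymptotic boundary (n_a = n_b = 6) the continuity-
        # corrected normal approximation stays close to enumeration
        errs = [
            abs(
                _wilcoxon_exact_p(x := rng.normal(0, 1, 6), y := rng.normal(0.5, 1, 6))
                - _wilcoxon_normal_p(x, y)
            )
            for _ in range(30)
        ]
        # the approximation is good to about one percentage point here;
        # agreement tightens rapidly as n grows
        assert np.median(errs) < 0.015
        assert max(errs) < 0.02

    def test_asymptotic_matches_scipy_with_ties(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(30):
            a = rng.integers(0, 6, 20).astype(float)
            b = rng.integers(0, 6, 25).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            _, p = wilcoxon_test(a, b)
            expected = mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
            assert p == pytest.approx(expected, abs=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_test([], [1, 2])


def _diff_setup(rng, n_per_group=10, de_gene=None, modality="rna", n_genes=20):
    genes = [f"g{i}" for i in range(n_genes)]
    cells, cols = [], []
    calls = [
        FateBiasCall("cloneA", "L", 10, 0, 0, 10, 2.0, 0.01, 0.01, "L biased"),
        FateBiasCall("cloneB", "E", 10, 0, 0, 10, 2.0, 0.01, 0.01, "E biased"),
    ]
    values = rng.poisson(5, size=(n_genes, 2 * n_per_group)).astype(float)
    for k in range(2 * n_per_group):
        clone = "cloneA" if k < n_per_group else "cloneB"
        cells.append(CellRecord(f"cell{k}", "HSPC", clone_id=clone))
        cols.append(f"cell{k}")
    if de_gene is not None:
        values[de_gene, :n_per_group] *= 8
    counts = CountMatrix(genes, cols, values.astype(int), modality=modality)
    return counts, cells, calls


class TestFateBiasDiff:
    def test_planted_gene_top_ranked(self, rng):
        counts, cells, calls = _diff_setup(rng, de_gene=3)
        results = fate_bias_diff(counts, cells, calls, "HSPC", "L", "E")
        assert results[0].feature_id == "g3"
        assert results[0].significant

    def test_p_cut_zero_nothing_significant(self, rng):
        counts, cells, calls = _diff_setup(rng, de_gene=3)
        results = fate_bias_diff(counts, cells, calls, "HSPC", "L", "E", p_cut=0.0)
        assert not any(r.significant for r in results)

    def test_small_group_errors_naming_group(self, rng):
        counts, cells, calls = _diff_setup(rng, n_per_group=2)
        with pytest.raises(ValueError, match="L biased"):
            fate_bias_diff(counts, cells, calls, "HSPC", "L", "E")

    def test_atac_modality_uses_rank_test(self, rng):
        counts, cells, calls = _diff_setup(rng, de_gene=1, modality="atac")
        results = fate_bias_diff(counts, cells, calls, "HSPC", "L", "E")
        assert results[0].feature_id == "g1"

    def test_accepts_full_bias_labels(self, rng):
        counts, cells, calls = _diff_setup(rng, de_gene=2)
        a = fate_bias_diff(counts, cells, calls, "HSPC", "L biased", "E biased")
        b = fate_bias_diff(counts, cells, calls, "HSPC", "L", "E")
        assert [r.feature_id for r in a] == [r.feature_id for r in b]


class TestPlantedDeRecovery:
    def test_planted_de_genes_recovered_on_synthetic_experiment(self):
        """50-gene panel with 10 planted 4-fold genes: all recovered, few
        false positives, using true clone assignments and called fate biases."""
        import dataclasses

        from clonetrace.fate import clone_fate_bias
        from clonetrace.simulate import benchmark_config, simulate_experiment

        for seed in (91, 92):
            exp = simulate_experiment(
                benchmark_config(seed, n_genes=50, n_de_genes=10),
                include_motifs=False,
            )
            calls = clone_fate_bias(exp.clone_matrix)
            with_clones = [
                dataclasses.replace(c, clone_id=exp.truth.cell_clone[c.cell_id])
                for c in exp.cells
            ]
            t_a, t_b = exp.truth.contrast_targets
            results = fate_bias_diff(
                exp.counts, with_clones, calls, exp.config.type_names[0], t_a, t_b
            )
            significant = {r.feature_id for r in results if r.significant}
            planted = set(exp.truth.de_genes)
            assert len(planted & significant) >= 9
            assert len(significant - planted) <= 2


class TestVolcano:
    def test_mappings_and_caps(self):
        results = [
            DiffResult("g1", 1, 1, 0.0, 1.0, False),
            DiffResult("g2", 9, 1, 3.0, 1e-300, True),
            DiffResult("g3", 1, 9, -2.0, 0.0, True),
        ]
        df = volcano_table(results).set_index("feature_id")
        assert df.loc["g1", "neg_log10_p"] == 0.0
        assert df.loc["g2", "neg_log10_p"] == pytest.approx(300.0)
        assert df.loc["g3", "neg_log10_p"] == 300.0
        assert df.loc["g3", "log2_fold_change"] == -2.0


def test_nearest_tss_assignment():
    peaks = [PeakRegion("chr1", 100, 200, "p1"), PeakRegion("chr2", 0, 50, "p2")]
    genes = [
        PeakRegion("chr1", 140, 1000, "geneA"),
        PeakRegion("chr1", 900, 2000, "geneB"),
    ]
    mapping = nearest_tss_genes(peaks, genes)
    assert mapping == {"p1": "geneA"}
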