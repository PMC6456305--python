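"""Two-locus heterogeneity scan and multi-locus additivity/epistasis tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, chi2_contingency

import cryptomap as cm
from cryptomap.hmm import from_truth
from cryptomap.interactions import (
    additivity_test,
    end_exclusion_mask,
    multilocus_expected,
    two_locus_scan,
)
from cryptomap.markers import P1
from conftest import tiny_map


def geno_on(mm, calls):
    return from_truth(mm, np.asarray(calls, dtype=np.int8))


class TestTwoLocusScan:
    def test_end_exclusion(self):
        mm = tiny_map([10_000, 50_000, 100_000, 195_000], chrom_length=200_000)
        keep = end_exclusion_mask(mm, 30_000)
        assert keep.tolist() == [False, True, True, False]  # 10 kb and 5 kb from ends

    def test_perfect_coupling_chi2_100(self, rng):
        # perfectly coupled pair, n = 100, both allele frequencies 0.5: all four
        # expected cells are 25 and chi2 = sum (O - E)^2 / E = 100.  (Identical
        # vectors would collapse into one group, so couple BY with 3S.)
        mm = tiny_map([50_000, 400_000], chrom_length=600_000)
        a = rng.permutation(np.repeat([0, 1], 50)).astype(np.int8)
        calls = np.column_stack([a, 1 - a])
        pairs = two_locus_scan(geno_on(mm, calls), fdr=1e-4, end_exclusion=30_000)
        assert len(pairs) == 1
        assert pairs["chi2"].iloc[0] == pytest.approx(100.0, abs=1e-9)
        assert bool(pairs["significant"].iloc[0])

    def test_independent_loci_not_reported(self, rng):
        mm = tiny_map([50_000, 400_000], chrom_length=600_000)
        calls = rng.integers(0, 2, size=(200, 2)).astype(np.int8)
        pairs = two_locus_scan(geno_on(mm, calls), fdr=1e-4, end_exclusion=30_000)
        assert not pairs["significant"].any()

    def test_monomorphic_group_skipped(self, rng):
        mm = tiny_map([50_000, 300_000, 400_000], chrom_length=600_000)
        calls = np.column_stack(
            [np.zeros(100, np.int8), rng.integers(0, 2, 100), rng.integers(0, 2, 100)]
        ).astype(np.int8)
        pairs = two_locus_scan(geno_on(mm, calls), fdr=1e-4, end_exclusion=30_000)
        fixed_id = mm.marker_ids[0]
        assert fixed_id not in set(pairs["marker_a"]) | set(pairs["marker_b"])

    def test_matches_pearson_independence_statistic(self, rng):
        # product-of-margins expectation == textbook Pearson chi2 on the 2x2 table
        mm = tiny_map([50_000, 400_000], chrom_length=600_000)
        for _ in range(50):
            calls = rng.integers(0, 2, size=(80, 2)).astype(np.int8)
            if len(np.unique(calls[:, 0])) < 2 or len(np.unique(calls[:, 1])) < 2:
                continue
            pairs = two_locus_scan(geno_on(mm, calls), fdr=1e-4, end_exclusion=30_000)
            table = pd.crosstab(calls[:, 0], calls[:, 1]).to_numpy()
            expected = chi2_contingency(table, correction=False)[0]
            assert pairs["chi2"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_bh_matches_brute_force(self, rng):
        # q-values monotone in P; significant set equals brute-force BH
        mm = tiny_map(
            sorted(rng.choice(np.arange(40_000, 560_000), 8, replace=False)),
            chrom_length=600_000,
        )
        calls = rng.integers(0, 2, size=(60, 8)).astype(np.int8)
        calls[:, 1] = calls[:, 0]  # one strongly coupled pair
        fdr = 0.05
        pairs = two_locus_scan(geno_on(mm, calls), fdr=fdr, end_exclusion=30_000)
        p = pairs["p_value"].to_numpy()
        order = np.argsort(p)
        mtests = len(p)
        q_sorted = np.minimum.accumulate((p[order] * mtests / np.arange(1, mtests + 1))[::-1])[::-1]
        brute_sig = np.zeros(mtests, bool)
        brute_sig[order] = q_sorted <= fdr
        assert (pairs["significant"].to_numpy() == brute_sig).all()
        ranked_q = pairs.sort_values("p_value")["q_value"].to_numpy()
        assert (np.diff(ranked_q) >= -1e-12).all()


class TestAlleleCombinations:
    def test_single_fixed_locus_single_class(self):
        mm = tiny_map([50_000], chrom_length=600_000)
        combos = cm.infer_allele_combinations(
            geno_on(mm, np.zeros((30, 1))), [mm.marker_ids[0]]
        )
        assert len(combos) == 1
        assert combos["count"].iloc[0] == 30
        assert combos["combination"].iloc[0] == "BY"

    def test_and_rule_selection_concentrates_one_combination(self):
        mm = cm.build_marker_map(2, 400_000, 200, seed=70)
        l1 = mm.nearest_marker("chr1", 200_000)
        l2 = mm.nearest_marker("chr2", 200_000)
        model = cm.TraitModel(
            "gp", "rule_based", rules=(cm.TraitRule({l1: P1, l2: P1}, 21),)
        )
        parent = cm.make_rough_parent(mm, model, seed=71)
        pop = cm.assign_phenotypes(
            cm.make_backcross(parent, "3S", 800, mm, 3e-6, seed=72), model
        )
        sel = cm.select_rough(pop, "any")
        combos = cm.infer_allele_combinations(from_truth(mm, sel.genotypes), [l1, l2])
        assert combos["combination"].iloc[0] == "BY/BY"
        assert combos["frequency"].iloc[0] == 1.0

    def test_two_rules_give_two_classes(self):
        mm = cm.build_marker_map(2, 400_000, 200, seed=70)
        l1 = mm.nearest_marker("chr1", 200_000)
        l2 = mm.nearest_marker("chr2", 200_000)
        model = cm.TraitModel(
            "gp",
            "rule_based",
            rules=(cm.TraitRule({l1: P1}, 21), cm.TraitRule({l2: P1}, 21)),
        )
        parent = cm.make_rough_parent(mm, model, seed=71)
        pop = cm.assign_phenotypes(
            cm.make_backcross(parent, "3S", 800, mm, 3e-6, seed=73), model
        )
        sel = cm.select_rough(pop, "any")
        combos = cm.infer_allele_combinations(from_truth(mm, sel.genotypes), [l1, l2])
        # all combinations except 3S/3S can express the trait
        assert set(combos["combination"]) == {"BY/BY", "BY/3S", "3S/BY"}


class TestMultilocusExpected:
    def test_product_rule(self):
        expected = multilocus_expected(np.array([0.6, 0.7]), 100)
        assert expected[0] == pytest.approx(42.0)  # P1P1: 100 * 0.6 * 0.7

    def test_uniform_frequencies(self):
        expected = multilocus_expected(np.full(3, 0.5), 80)
        assert np.allclose(expected, 10.0)

    def test_normalization_property(self, rng):
        for _ in range(20):
            f = rng.uniform(0.05, 0.95, size=rng.integers(2, 6))
            n = int(rng.integers(10, 500))
            assert multilocus_expected(f, n).sum() == pytest.approx(n, abs=1e-9)

    def test_monomorphic_frequency_rejected(self):
        with pytest.raises(ValueError):
            multilocus_expected(np.array([0.0, 0.5]), 50)


class TestAdditivityTest:
    def test_observed_equals_expected(self):
        e = multilocus_expected(np.array([0.5, 0.5]), 64)
        res = additivity_test(e.copy(), e)
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_df_rule_three_loci(self):
        e = multilocus_expected(np.full(3, 0.5), 80)
        res = additivity_test(e.copy(), e)
        assert res.df == 7  # 2^3 - 1

    def test_monte_carlo_close_to_asymptotic_for_moderate_counts(self, rng):
        expected = multilocus_expected(np.array([0.55, 0.3]), 40)
        observed = rng.multinomial(40, expected / 40).astype(float)
        res = additivity_test(observed, expected, mc_reps=4000, seed=9)
        if res.any_small_expected:
            assert abs(res.p_monte_carlo - res.p_value) < 0.1

    def test_not_applicable_below_two_loci(self):
        mm = tiny_map([50_000, 400_000], chrom_length=600_000)
        calls = np.zeros((40, 2), np.int8)  # both loci fixed
        res = cm.additivity_analysis(from_truth(mm, calls), list(mm.marker_ids))
        assert not res.applicable
        assert "fewer than two" in res.reason

    def test_type_one_error_under_true_independence(self):
        # 500 null replicates of independent loci: rejection rate <= nominal + 3 s.e.
        rng = np.random.default_rng(77)
        mm = tiny_map([50_000, 250_000, 450_000], chrom_length=600_000)
        freqs = np.array([0.5, 0.4, 0.6])
        rejections = 0
        for _ in range(500):
            calls = (rng.random((150, 3)) > freqs).astype(np.int8)  # P2 with 1 - f
            res = cm.additivity_analysis(from_truth(mm, calls), list(mm.marker_ids))
            if res.applicable and res.p_value < 0.05:
                rejections += 1
        assert rejections / 500 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 500)

    def test_discriminates_architectures(self):
        from cryptomap.validation import additivity_discrimination_experiment

        additive = additivity_discrimination_experiment(
            "additive", n_replicates=25, n_selected=150, seed=3
        )
        epistatic = additivity_discrimination_experiment(
            "epistatic", n_replicates=25, n_selected=150, seed=3
        )
        assert additive.rate <= 0.1  # retains the null
        assert epistatic.rate >= 0.9  # rejects
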