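"""Cross-simulator contracts: marker maps, meiosis, backcrosses, phenotypes, coverage."""

import numpy as np
import pytest

import cryptomap as cm
from cryptomap.markers import P1, P2
from cryptomap.simulate import CLASSES
from conftest import tiny_map


class TestMarkerMap:
    def test_construction_contract(self):
        mm = cm.build_marker_map(1, 10**6, 100, seed=1)
        assert mm.n_markers == 100
        pos = mm.positions("chr1")
        assert (np.diff(pos) > 0).all()
        assert len(set(mm.marker_ids)) == 100

    def test_determinism(self):
        a = cm.build_marker_map(16, 10**6, 2000, seed=7)
        b = cm.build_marker_map(16, 10**6, 2000, seed=7)
        assert a.table.equals(b.table)

    def test_pigeonhole_error(self):
        with pytest.raises(ValueError):
            cm.build_marker_map(1, 10, 20, seed=0)

    def test_fewer_markers_than_chromosomes(self):
        with pytest.raises(ValueError):
            cm.build_marker_map(4, 1000, 3, seed=0)


class TestMeiosis:
    def test_identical_parents_identity(self, rng):
        mm = cm.build_marker_map(2, 10**5, 50, seed=3)
        parent = rng.integers(0, 2, mm.n_markers).astype(np.int8)
        gamete = cm.simulate_gamete(parent, parent, mm, 1e-5, seed=9)
        assert (gamete == parent).all()

    def test_zero_rate_whole_chromosome_from_one_parent(self):
        mm = cm.build_marker_map(3, 10**5, 60, seed=3)
        a = np.zeros(mm.n_markers, dtype=np.int8)
        b = np.ones(mm.n_markers, dtype=np.int8)
        gametes = cm.simulate_gametes(a, b, mm, 0.0, 200, seed=4)
        for chrom in mm.chrom_names:
            sl = mm.chrom_slice(chrom)
            block = gametes[:, sl]
            assert ((block == 0).all(axis=1) | (block == 1).all(axis=1)).all()

    def test_negative_rate_rejected(self):
        mm = cm.build_marker_map(1, 1000, 5, seed=0)
        a = np.zeros(5, dtype=np.int8)
        with pytest.raises(ValueError):
            cm.simulate_gametes(a, a, mm, -1e-6, 1, seed=0)

    def test_haldane_limit_large_distance(self):
        # two markers a huge map distance apart: discordance -> 1/2
        mm = tiny_map([1, 10**6], chrom_length=2 * 10**6)
        a = np.array([0, 0], dtype=np.int8)
        b = np.array([1, 1], dtype=np.int8)
        gametes = cm.simulate_gametes(a, b, mm, 1e-4, 10_000, seed=11)  # d = 100 Morgans
        discordance = (gametes[:, 0] != gametes[:, 1]).mean()
        assert discordance == pytest.approx(0.5, abs=3 * 0.005)  # 3 s.e. of 1e4 draws

    def test_linkage_decay_monotone(self):
        # allele correlation falls with genetic distance (3 distances, 1e4 gametes)
        mm = tiny_map([1, 20_001, 100_001, 500_001], chrom_length=10**6)
        a = np.zeros(4, dtype=np.int8)
        b = np.ones(4, dtype=np.int8)
        gametes = cm.simulate_gametes(a, b, mm, 3e-6, 10_000, seed=12)
        corrs = [np.corrcoef(gametes[:, 0], gametes[:, j])[0, 1] for j in (1, 2, 3)]
        assert corrs[0] > corrs[1] > corrs[2]


class TestBackcross:
    def test_fixed_cross_all_recurrent(self):
        mm = cm.build_marker_map(2, 10**5, 40, seed=5)
        rough = np.ones(mm.n_markers, dtype=np.int8)
        pop = cm.make_backcross(rough, "3S", 50, mm, 3e-6, seed=6)
        assert (pop.genotypes == P2).all()

    def test_mendelian_segregation(self):
        # heterozygous-origin markers: allele frequency 0.5 within 3 s.e. at n=1000
        mm = cm.build_marker_map(4, 250_000, 400, seed=5)
        rough = np.zeros(mm.n_markers, dtype=np.int8)  # all-BY rough parent
        pop = cm.make_backcross(rough, "3S", 1000, mm, 3e-6, seed=7)
        freqs = (pop.genotypes == P1).mean(axis=0)
        se3 = 3 * np.sqrt(0.25 / 1000)
        assert (np.abs(freqs - 0.5) <= se3).mean() > 0.99
        assert abs(freqs.mean() - 0.5) < se3  # genome-wide average well inside the band

    def test_fixed_marker_zero_variance(self):
        mm = cm.build_marker_map(1, 10**5, 30, seed=5)
        rough = np.ones(mm.n_markers, dtype=np.int8)
        rough[:10] = 0
        pop = cm.make_backcross(rough, "3S", 300, mm, 3e-6, seed=8)
        fixed = rough == P2
        assert pop.genotypes[:, fixed].var(axis=0).max() == 0.0


class TestPhenotypes:
    @pytest.fixture
    def rule_setup(self):
        mm = cm.build_marker_map(2, 200_000, 100, seed=9)
        l1 = mm.nearest_marker("chr1", 100_000)
        l2 = mm.nearest_marker("chr2", 100_000)
        model = cm.TraitModel(
            "gp", "rule_based",
            rules=(cm.TraitRule({l1: P2, l2: P1}, max_temperature=30),),
        )
        return mm, model, l1, l2

    def test_rule_temperature_class(self, rule_setup):
        # carrier of a max-30 rule is rough at 21 and 30 but smooth at 37
        mm, model, l1, l2 = rule_setup
        geno = np.zeros((2, mm.n_markers), dtype=np.int8)
        geno[0, mm.index_of(l1)] = P2  # carrier: (P2, P1)
        geno[1, mm.index_of(l2)] = P2  # non-carrier
        pop = cm.Population(mm, geno, rough_parent=np.zeros(mm.n_markers, np.int8), recurrent=P1)
        pop = cm.assign_phenotypes(pop, model)
        assert pop.phenotypes.loc[0, ["rough21", "rough30", "rough37"]].tolist() == [True, True, False]
        assert pop.phenotypes.loc[0, "tclass"] == "30"
        assert not pop.phenotypes.loc[1, "rough21"]

    def test_rule_monotone_in_temperature(self, rule_setup):
        mm, model, _, _ = rule_setup
        rough = cm.make_rough_parent(mm, model, seed=1)
        pop = cm.make_backcross(rough, "3S", 500, mm, 3e-6, seed=2)
        phen = cm.assign_phenotypes(pop, model).phenotypes
        assert (phen["rough30"] <= phen["rough21"]).all()
        assert (phen["rough37"] <= phen["rough30"]).all()

    def test_multiplicative_baseline_no_favored_alleles(self):
        mm = cm.build_marker_map(1, 100_000, 50, seed=9)
        locus = mm.nearest_marker("chr1", 50_000)
        model = cm.TraitModel(
            "gp", "multiplicative", baseline=0.01, effects={locus: (P1, 5.0)}
        )
        geno = np.full((200_000, mm.n_markers), P2, dtype=np.int8)  # zero favored alleles
        pop = cm.Population(mm, geno, np.zeros(mm.n_markers, np.int8), P1)
        phen = cm.assign_phenotypes(pop, model, seed=3).phenotypes
        rate = phen["rough21"].mean()
        assert rate == pytest.approx(0.01, abs=3 * np.sqrt(0.01 * 0.99 / 200_000))

    def test_multiplicative_never_rough_at_higher_temperatures(self):
        mm = cm.build_marker_map(1, 100_000, 50, seed=9)
        locus = mm.nearest_marker("chr1", 50_000)
        model = cm.TraitModel("gp", "multiplicative", baseline=0.5, effects={locus: (P1, 2.0)})
        rough = cm.make_rough_parent(mm, model, seed=4)
        pop = cm.make_backcross(rough, "3S", 400, mm, 3e-6, seed=5)
        phen = cm.assign_phenotypes(pop, model, seed=6).phenotypes
        assert not phen["rough30"].any() and not phen["rough37"].any()

    def test_unknown_locus_rejected(self):
        mm = cm.build_marker_map(1, 100_000, 50, seed=9)
        model = cm.TraitModel(
            "gp", "rule_based", rules=(cm.TraitRule({"nope_1": P1}, 21),)
        )
        pop = cm.make_backcross(np.zeros(50, np.int8), "3S", 10, mm, 3e-6, seed=1)
        with pytest.raises(KeyError):
            cm.assign_phenotypes(pop, model)


class TestSelection:
    def test_all_smooth_gives_empty_selection(self):
        mm = cm.build_marker_map(1, 100_000, 40, seed=10)
        locus = mm.nearest_marker("chr1", 50_000)
        model = cm.TraitModel("gp", "rule_based", rules=(cm.TraitRule({locus: P1}, 21),))
        geno = np.full((30, mm.n_markers), P2, dtype=np.int8)
        pop = cm.Population(mm, geno, np.zeros(mm.n_markers, np.int8), P1)
        pop = cm.assign_phenotypes(pop, model)
        assert cm.select_rough(pop, "any").n_segregants == 0

    def test_exact_class_excludes_broader_expression(self):
        mm = cm.build_marker_map(1, 100_000, 40, seed=10)
        locus = mm.nearest_marker("chr1", 50_000)
        model = cm.TraitModel("gp", "rule_based", rules=(cm.TraitRule({locus: P1}, 37),))
        geno = np.full((5, mm.n_markers), P1, dtype=np.int8)  # all rough at 21/30/37
        pop = cm.Population(mm, geno, np.zeros(mm.n_markers, np.int8), P1)
        pop = cm.assign_phenotypes(pop, model)
        assert cm.select_rough(pop, "21").n_segregants == 0
        assert cm.select_rough(pop, "37").n_segregants == 5

    def test_invalid_filter_rejected(self):
        mm = cm.build_marker_map(1, 100_000, 40, seed=10)
        pop = cm.Population(
            mm, np.zeros((3, 40), np.int8), np.zeros(40, np.int8), P1
        )
        pop = cm.assign_phenotypes(
            pop,
            cm.TraitModel("gp", "rule_based",
                          rules=(cm.TraitRule({mm.marker_ids[0]: P1}, 21),)),
        )
        with pytest.raises(ValueError):
            cm.select_rough(pop, "25")

    def test_classes_partition_rough_segregants(self):
        mm = cm.build_marker_map(2, 300_000, 200, seed=10)
        model = cm.TraitModel(
            "gp", "rule_based",
            rules=(
                cm.TraitRule({mm.nearest_marker("chr1", 100_000): P1}, 21),
                cm.TraitRule({mm.nearest_marker("chr2", 100_000): P1}, 37),
            ),
        )
        rough = cm.make_rough_parent(mm, model, seed=2)
        pop = cm.assign_phenotypes(cm.make_backcross(rough, "3S", 600, mm, 3e-6, 3), model)
        total = sum(cm.select_rough(pop, c).n_segregants for c in CLASSES)
        assert total == cm.select_rough(pop, "any").n_segregants


class TestReadCounts:
    def test_zero_coverage_all_empty(self):
        mm = cm.build_marker_map(1, 10**5, 30, seed=11)
        pop = cm.make_backcross(np.zeros(30, np.int8), "3S", 20, mm, 3e-6, 1)
        counts = cm.simulate_read_counts(pop, 0.0, 0.01, seed=2)
        assert counts.depth.max() == 0

    def test_error_free_counts_match_truth(self):
        mm = cm.build_marker_map(1, 10**5, 30, seed=11)
        pop = cm.make_backcross(np.zeros(30, np.int8), "3S", 50, mm, 3e-6, 1)
        counts = cm.simulate_read_counts(pop, 3.0, 0.0, seed=3)
        p1_sites = pop.genotypes == P1
        assert (counts.n_p2[p1_sites] == 0).all()
        assert (counts.n_p1[~p1_sites] == 0).all()

    def test_poisson_mean_coverage(self):
        # 1e4 site-segregant draws at mean 2.5: empirical mean within 3 s.e.
        mm = cm.build_marker_map(1, 10**6, 100, seed=11)
        pop = cm.make_backcross(np.zeros(100, np.int8), "3S", 100, mm, 3e-6, 1)
        counts = cm.simulate_read_counts(pop, 2.5, 0.002, seed=4)
        mean = counts.depth.mean()
        se3 = 3 * np.sqrt(2.5 / counts.depth.size)
        assert mean == pytest.approx(2.5, abs=se3)

    def test_invalid_error_rate(self):
        mm = cm.build_marker_map(1, 10**5, 10, seed=11)
        pop = cm.make_backcross(np.zeros(10, np.int8), "3S", 5, mm, 3e-6, 1)
        with pytest.raises(ValueError):
            cm.simulate_read_counts(pop, 2.5, 0.6, seed=0)


def test_operations_bit_reproducible():
    """Every stochastic operation yields identical output for identical seeds."""
    mm1 = cm.build_marker_map(2, 10**5, 80, seed=21)
    mm2 = cm.build_marker_map(2, 10**5, 80, seed=21)
    rough = np.zeros(80, np.int8)
    p1 = cm.make_backcross(rough, "3S", 40, mm1, 3e-6, seed=22)
    p2 = cm.make_backcross(rough, "3S", 40, mm2, 3e-6, seed=22)
    assert (p1.genotypes == p2.genotypes).all()
    c1 = cm.simulate_read_counts(p1, 2.5, 0.002, seed=23)
    c2 = cm.simulate_read_counts(p2, 2.5, 0.002, seed=23)
    assert (c1.n_p1 == c2.n_p1).all() and (c1.n_p2 == c2.n_p2).all()
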