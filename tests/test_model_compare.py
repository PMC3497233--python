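"""Mean squared distance statistic and the paired-label permutation test."""

import numpy as np
import pytest
from scipy.stats import kstest

from treecongruence.model_compare import (
    PairedTreeSets,
    compare_report,
    cross_model_distance_matrix,
    mean_squared_distance,
    permutation_test,
    _stat_from_selection,
)
from treecongruence.synthetic_data import GeneTreeSimConfig, simulate_paired_models
from treecongruence.treeio import parse_newick


def _null_pairs(seed, gene_count=20):
    cfg = GeneTreeSimConfig(gene_count=gene_count, outlier_count=0, seed=seed)
    return simulate_paired_models(cfg, 1.0)


class TestMeanSquaredDistance:
    def test_identical_trees_zero(self):
        t = parse_newick("((A:0.1,B:0.1):0.3,C:0.1,D:0.1);")
        assert mean_squared_distance([t.copy() for _ in range(4)]) == 0.0

    def test_single_pair_squares_the_distance(self, quartet_ab_cd, quartet_ac_bd):
        # the two quartets are at geodesic distance 0.7
        assert mean_squared_distance(
            [quartet_ab_cd, quartet_ac_bd]) == pytest.approx(0.49, abs=1e-12)

    def test_three_same_topology_trees_average_squared_euclidean(self):
        base = "((A:0.1,B:0.1):{x},C:0.1,D:0.1);"
        trees = [parse_newick(base.format(x=x)) for x in (0.0, 0.1, 0.3)]
        # pairwise distances {0.1, 0.3, 0.2} -> mean square 0.14/3
        assert mean_squared_distance(trees) == pytest.approx(0.14 / 3, abs=1e-12)

    def test_fewer_than_two_trees_rejected(self, quartet_ab_cd):
        with pytest.raises(ValueError):
            mean_squared_distance([quartet_ab_cd])


class TestPairedTreeSets:
    def test_missing_tree_named_in_error(self):
        t = parse_newick("((A:0.1,B:0.1):0.3,C:0.1,D:0.1);")
        with pytest.raises(ValueError, match="g1"):
            PairedTreeSets(genes=["g0", "g1"], model_a="A", model_b="B",
                           trees_a=[t, None], trees_b=[t, t])

    def test_taxon_set_mismatch_named_in_error(self):
        t = parse_newick("((A:0.1,B:0.1):0.3,C:0.1,D:0.1);")
        u = parse_newick("((A:0.1,B:0.1):0.3,C:0.1,E:0.1);")
        with pytest.raises(Exception, match="g1"):
            PairedTreeSets(genes=["g0", "g1"], model_a="A", model_b="B",
                           trees_a=[t, u], trees_b=[t, t])


class TestPermutationTest:
    def test_identical_sets_give_p_one_at_any_seed(self):
        t = parse_newick("((A:0.1,B:0.1):0.3,C:0.1,D:0.1);")
        trees = [t.copy(name=f"g{i}") for i in range(6)]
        pairs = PairedTreeSets(genes=[f"g{i}" for i in range(6)],
                               model_a="A", model_b="B",
                               trees_a=trees, trees_b=[u.copy() for u in trees])
        for seed in (0, 1, 99):
            r = permutation_test(pairs, n_perm=199, seed=seed)
            assert r.difference == pytest.approx(0.0, abs=1e-12)
            assert r.p_value == 1.0

    def test_p_resolution_and_bounds(self):
        r = permutation_test(_null_pairs(0), n_perm=99, seed=3)
        assert 0 < r.p_value <= 1
        assert round(r.p_value * 100, 9) == int(round(r.p_value * 100))

    def test_input_validation(self):
        pairs = _null_pairs(1, gene_count=4)
        with pytest.raises(ValueError, match="5 genes"):
            permutation_test(pairs, n_perm=999, seed=0)
        with pytest.raises(ValueError, match="99"):
            permutation_test(_null_pairs(1), n_perm=50, seed=0)

    def test_seed_replay_reproduces_identical_result(self):
        pairs = _null_pairs(2)
        r1 = permutation_test(pairs, n_perm=499, seed=11)
        r2 = permutation_test(pairs, n_perm=499, seed=11)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.perm_stats, r2.perm_stats)

    def test_label_swap_negates_difference_and_keeps_two_sided_p(self):
        pairs = _null_pairs(4)
        swapped = PairedTreeSets(genes=pairs.genes, model_a=pairs.model_b,
                                 model_b=pairs.model_a, trees_a=pairs.trees_b,
                                 trees_b=pairs.trees_a)
        r = permutation_test(pairs, n_perm=299, seed=5)
        rs = permutation_test(swapped, n_perm=299, seed=5)
        assert rs.difference == pytest.approx(-r.difference, abs=1e-12)
        # exact p equality via the corresponding (complemented) flip sequence:
        # each flip pattern f on the swapped pairs equals pattern 1-f on the
        # originals, so the |difference| permutation distributions coincide
        g = len(pairs)
        d2 = cross_model_distance_matrix(pairs) ** 2
        base = np.arange(g)
        rng = np.random.default_rng(5)
        flips = rng.integers(0, 2, size=(299, g))
        orig = np.array([
            _stat_from_selection(d2, base + g * f) -
            _stat_from_selection(d2, base + g * (1 - f)) for f in flips])
        swap = np.array([
            _stat_from_selection(d2, base + g * (1 - f)) -
            _stat_from_selection(d2, base + g * f) for f in flips])
        obs = _stat_from_selection(d2, base) - _stat_from_selection(d2, base + g)
        eps = 1e-12
        p_orig = (1 + np.sum(np.abs(orig) >= abs(obs) - eps)) / 300
        p_swap = (1 + np.sum(np.abs(swap) >= abs(obs) - eps)) / 300
        assert p_orig == p_swap

    def test_null_p_values_not_anticonservative(self):
        # under exchangeable pairs the p distribution should be (weakly)
        # stochastically >= uniform
        ps = []
        for seed in range(100):
            pairs = _null_pairs(10_000 + seed, gene_count=12)
            ps.append(permutation_test(pairs, n_perm=199, seed=seed).p_value)
        stat = kstest(ps, "uniform", alternative="greater")
        assert stat.pvalue > 0.01

    def test_power_monotone_in_noise_multiplier(self):
        rates = []
        for mult in (1.0, 2.0, 3.0):
            rej = 0
            for seed in range(25):
                cfg = GeneTreeSimConfig(gene_count=15, outlier_count=0,
                                        seed=20_000 + seed)
                pairs = simulate_paired_models(cfg, mult)
                rej += permutation_test(pairs, n_perm=199, seed=seed).p_value <= 0.05
            rates.append(rej / 25)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_one_sided_tails_partition_the_difference(self):
        pairs = simulate_paired_models(
            GeneTreeSimConfig(gene_count=10, outlier_count=0, seed=42), 3.0)
        less = permutation_test(pairs, n_perm=199, seed=1, tail="one-less")
        greater = permutation_test(pairs, n_perm=199, seed=1, tail="one-greater")
        # model A has less noise, so its statistic is lower
        assert less.p_value < 0.05
        assert greater.p_value > 0.5


class TestCompareReport:
    def test_identical_sets_render_zero_versus_zero(self):
        t = parse_newick("((A:0.1,B:0.1):0.3,C:0.1,D:0.1);")
        trees = [t.copy(name=f"g{i}") for i in range(5)]
        pairs = PairedTreeSets(genes=[f"g{i}" for i in range(5)],
                               model_a="A", model_b="B",
                               trees_a=trees, trees_b=[u.copy() for u in trees])
        rep = compare_report(permutation_test(pairs, n_perm=99, seed=0))
        assert rep["summary"] == "0 versus 0; p = 1"

    def test_report_carries_seed_and_quantiles(self):
        r = permutation_test(_null_pairs(6), n_perm=199, seed=7)
        rep = compare_report(r)
        assert rep["seed"] == 7
        assert rep["permutations"] == 199
        qs = rep["permutation_distribution_quantiles"]
        assert qs["q025"] <= qs["q500"] <= qs["q975"]

    def test_null_permutation_distribution_centred_at_zero(self):
        r = permutation_test(_null_pairs(8, gene_count=25), n_perm=999, seed=9)
        se = r.perm_stats.std() / np.sqrt(len(r.perm_stats))
        assert abs(r.perm_stats.mean()) < 2 * se + 1e-3
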