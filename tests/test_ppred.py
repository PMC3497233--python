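"""Adequacy statistics, Fitch parsimony and the central-95% rule."""

import itertools

import numpy as np
import pytest

from treecongruence.ppred import (
    Alignment,
    composition_chi2,
    fitch_steps,
    homoplasy_index,
    nj_guide_tree,
    ppred_test,
    read_alignment,
    site_diversity,
)
from treecongruence.synthetic_data import (
    AlignmentSimConfig,
    simulate_alignment,
    simulate_species_tree,
)
from treecongruence.treeio import TaxonSet, TreeError, parse_newick, to_node_tree


def _aln(rows, labels=None, alphabet="ACGT"):
    labels = labels or [f"t{i}" for i in range(len(rows))]
    taxa = TaxonSet(labels)
    ordered = [rows[labels.index(lab)] for lab in taxa.labels]
    return Alignment(taxa=taxa, rows=ordered, alphabet=alphabet)


class TestCompositionChi2:
    def test_identical_rows_score_zero(self):
        assert composition_chi2(_aln(["ACGT", "ACGT"])) == 0.0

    def test_two_state_toy_equals_hand_value(self):
        # AAAA vs CCCC: each taxon expects 2 A's and 2 C's -> X^2 = 4*(2^2/2) = 8
        assert composition_chi2(_aln(["AAAA", "CCCC"])) == pytest.approx(8.0, abs=1e-12)

    def test_duplicating_rows_doubles_the_statistic(self):
        a = _aln(["AACG", "CCGT", "AGGT"], labels=["a", "b", "c"])
        b = _aln(["AACG", "CCGT", "AGGT", "AACG", "CCGT", "AGGT"],
                 labels=["a", "b", "c", "d", "e", "f"])
        assert composition_chi2(b) == pytest.approx(2 * composition_chi2(a), rel=1e-12)

    def test_gap_only_taxon_rejected(self):
        with pytest.raises(ValueError, match="zero ungapped"):
            composition_chi2(_aln(["ACGT", "----"]))

    def test_invariant_under_column_permutation(self):
        rows = ["ACGTAC", "AGGTAT", "CCGTAA"]
        a = _aln(rows, labels=["a", "b", "c"])
        perm = [3, 0, 5, 1, 4, 2]
        rows_p = ["".join(r[i] for i in perm) for r in rows]
        b = _aln(rows_p, labels=["a", "b", "c"])
        assert composition_chi2(a) == composition_chi2(b)


class TestSiteDiversity:
    def test_constant_columns_give_one(self):
        assert site_diversity(_aln(["AAAA", "AAAA", "AAAA"])) == 1.0

    def test_two_column_toy_equals_three(self):
        # columns (A,A,C,C) and (A,C,G,T) -> (2 + 4) / 2 = 3.0
        assert site_diversity(_aln(["AA", "AC", "CG", "CT"])) == pytest.approx(3.0)

    def test_gaps_excluded_from_state_counts(self):
        # column (A,A,A,-) counts a single distinct state
        assert site_diversity(_aln(["A", "A", "A", "-"])) == 1.0

    def test_gap_only_columns_dropped_and_all_gap_rejected(self):
        assert site_diversity(_aln(["A-", "A-", "C-"])) == 2.0
        with pytest.raises(ValueError, match="gap-only"):
            site_diversity(_aln(["--", "--"]))


def _brute_force_min_changes(column, guide):
    """Exhaustive minimum over all ancestral state assignments (small trees)."""
    root = to_node_tree(guide)
    internals, leaves = [], {}

    def collect(node):
        if node.leaf is None:
            internals.append(node)
            for ch in node.children:
                collect(ch)
    collect(root)
    k = 4
    best = np.inf
    for states in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(map(id, internals), states))

        def cost(node, parent_state):
            if node.leaf is not None:
                obs = column[node.leaf]
                if obs < 0:  # missing: free choice, so no constraint
                    return 0
                return int(obs != parent_state)
            s = assign[id(node)]
            return int(s != parent_state) + sum(cost(ch, s) for ch in node.children)

        root_state = assign[id(root)]
        total = sum(cost(ch, root_state) for ch in root.children)
        best = min(best, total)
    return int(best)


class TestFitchAndHomoplasy:
    def test_concordant_column_has_no_homoplasy(self):
        t = parse_newick("((t0:1,t1:1):1,t2:1,t3:1);")
        assert homoplasy_index(_aln(["A", "A", "C", "C"]), t) == 0

    def test_convergent_column_has_one_extra_step(self):
        t = parse_newick("((t0:1,t1:1):1,t2:1,t3:1);")
        assert homoplasy_index(_aln(["A", "C", "A", "C"]), t) == 1

    def test_guide_taxa_must_cover_alignment(self):
        t = parse_newick("((t0:1,t1:1):1,t2:1,t9:1);")
        with pytest.raises(TreeError, match="missing"):
            homoplasy_index(_aln(["A", "C", "A", "C"]), t)

    def test_guide_superset_is_projected(self):
        t = parse_newick("(((t0:1,t1:1):1,t4:1):1,t2:1,t3:1);")
        assert homoplasy_index(_aln(["A", "A", "C", "C"]), t) == 0

    def test_fitch_equals_brute_force_minimum_on_small_trees(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 500:
            n = int(rng.integers(4, 7))
            guide = simulate_species_tree(n, seed=int(rng.integers(2**31)))
            cols = rng.integers(0, 4, size=(8, n))
            cols[rng.random(cols.shape) < 0.1] = -1  # sprinkle missing data
            rows = ["".join("ACGT"[c] if c >= 0 else "-" for c in cols[:, i])
                    for i in range(n)]
            aln = Alignment(taxa=guide.taxa, rows=rows)
            steps = fitch_steps(aln, guide)
            for j in range(cols.shape[0]):
                assert steps[j] == _brute_force_min_changes(cols[j], guide)
                checked += 1

    def test_invariant_under_taxon_relabelling(self):
        guide = simulate_species_tree(6, seed=3)
        aln = simulate_alignment(AlignmentSimConfig(tree=guide, length=80, seed=5))
        # relabel taxa (guide relabelled accordingly): statistic unchanged
        mapping = {lab: f"x{i}" for i, lab in enumerate(reversed(guide.taxa.labels))}
        new_taxa = TaxonSet(mapping.values())
        order = sorted(guide.taxa.labels, key=lambda lab: mapping[lab])
        new_rows = [aln.rows[guide.taxa.index(lab)] for lab in order]
        relabeled_aln = Alignment(taxa=new_taxa, rows=new_rows)
        remap = {m: new_taxa.normalize(
            new_taxa.mask_of(mapping[lab] for lab in guide.taxa.labels_of(m)))
            for m in guide.split_lengths}
        from treecongruence.treeio import PhyloTree
        relabeled_guide = PhyloTree(new_taxa, {remap[m]: ln for m, ln
                                               in guide.split_lengths.items()})
        assert homoplasy_index(aln, guide) == homoplasy_index(
            relabeled_aln, relabeled_guide)
        assert site_diversity(aln) == site_diversity(relabeled_aln)

    def test_saturation_raises_homoplasy(self):
        guide = simulate_species_tree(8, seed=7)
        wins = 0
        for seed in range(30):
            plain = simulate_alignment(AlignmentSimConfig(
                tree=guide, length=100, seed=30_000 + seed))
            sat = simulate_alignment(AlignmentSimConfig(
                tree=guide.scaled(5.0), length=100, seed=30_000 + seed))
            wins += homoplasy_index(sat, guide) > homoplasy_index(plain, guide)
        assert wins >= 29


class TestPPredRule:
    def test_replicates_identical_to_observed_all_pass(self):
        guide = simulate_species_tree(6, seed=1)
        obs = simulate_alignment(AlignmentSimConfig(tree=guide, length=60, seed=2))
        reports = ppred_test(obs, [obs] * 25, guide=guide)
        assert all(r.passed for r in reports)

    def test_too_few_replicates_rejected(self):
        guide = simulate_species_tree(6, seed=1)
        obs = simulate_alignment(AlignmentSimConfig(tree=guide, length=60, seed=2))
        with pytest.raises(ValueError, match="20 replicate"):
            ppred_test(obs, [obs] * 19, guide=guide)

    def test_unknown_statistic_rejected(self):
        guide = simulate_species_tree(6, seed=1)
        obs = simulate_alignment(AlignmentSimConfig(tree=guide, length=60, seed=2))
        with pytest.raises(ValueError, match="unknown"):
            ppred_test(obs, [obs] * 25, statistics=("entropy",), guide=guide)

    def test_widening_to_central_99_never_turns_pass_into_fail(self):
        guide = simulate_species_tree(8, seed=4)
        obs = simulate_alignment(AlignmentSimConfig(tree=guide, length=150, seed=40))
        reps = [simulate_alignment(AlignmentSimConfig(tree=guide, length=150,
                                                      seed=41 + i))
                for i in range(40)]
        narrow = ppred_test(obs, reps, guide=guide, central=0.95)
        wide = ppred_test(obs, reps, guide=guide, central=0.99)
        for r95, r99 in zip(narrow, wide):
            if r95.passed:
                assert r99.passed

    def test_planted_compositional_heterogeneity_fails_chi2(self):
        guide = simulate_species_tree(8, seed=7)
        reps = [simulate_alignment(AlignmentSimConfig(tree=guide, length=300,
                                                      seed=50_000 + i))
                for i in range(30)]
        fails = 0
        for trial in range(10):
            shifted = simulate_alignment(AlignmentSimConfig(
                tree=guide, length=300, composition_shift=0.2,
                seed=60_000 + trial))
            rep = ppred_test(shifted, reps, statistics=("composition",), guide=guide)
            fails += not rep[0].passed
        assert fails == 10

    def test_default_guide_is_neighbor_joining(self):
        guide = simulate_species_tree(8, seed=7)
        obs = simulate_alignment(AlignmentSimConfig(tree=guide, length=300, seed=70))
        nj = nj_guide_tree(obs)
        assert nj.taxa == obs.taxa
        # the self-test with an NJ default guide must still pass trivially
        reports = ppred_test(obs, [obs] * 25)
        assert all(r.passed for r in reports)


class TestAlignmentIO:
    def test_fasta_roundtrip_in_canonical_order(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">zeta\nACGT\n>alpha\nACCT\n")
        aln = read_alignment(p)
        assert aln.taxa.labels == ("alpha", "zeta")
        assert aln.rows == ["ACCT", "ACGT"]

    def test_relaxed_phylip_read(self, tmp_path):
        p = tmp_path / "a.phy"
        p.write_text(" 2 4\nalpha  ACCT\nzeta   ACGT\n")
        aln = read_alignment(p)
        assert aln.taxa.labels == ("alpha", "zeta")
        assert aln.rows == ["ACCT", "ACGT"]

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            _aln(["ACGT", "ACG"])

    def test_characters_outside_alphabet_rejected(self):
        with pytest.raises(ValueError, match="outside alphabet"):
            composition_chi2(_aln(["AZGT", "ACGT"]))
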