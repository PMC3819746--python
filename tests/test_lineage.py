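"""Haplotypes, neighbor joining, the genealogical sorting index, and
Evanno's delta-K."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from _oracles import gsi_node_count_oracle
from specdelim import lineage
from specdelim.lineage import (
    LineageError,
    collapse_haplotypes,
    evanno_delta_k,
    gsi,
    gsi_test,
    nj_tree,
)


def tree_from(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True
    )


class TestHaplotypes:
    def test_collapse_counts_and_frequency_order(self):
        table = collapse_haplotypes({"a": "ACGT", "b": "ACGT", "c": "ACGA"})
        assert table.frequencies == {"H1": 2, "H2": 1}
        assert table.haplotypes["H1"] == "ACGT"
        assert table.assignment == {"a": "H1", "b": "H1", "c": "H2"}

    def test_all_unique_yields_n_haplotypes(self):
        seqs = {f"s{i}": "ACG" + b for i, b in enumerate("ACGT")}
        table = collapse_haplotypes(seqs)
        assert len(table.haplotypes) == 4
        assert sum(table.frequencies.values()) == 4

    def test_n_is_a_literal_character(self):
        table = collapse_haplotypes({"a": "ACNT", "b": "ACGT"})
        assert len(table.haplotypes) == 2

    def test_case_insensitive_identity(self):
        table = collapse_haplotypes({"a": "acgt", "b": "ACGT"})
        assert len(table.haplotypes) == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(LineageError, match="aligned"):
            collapse_haplotypes({"a": "ACGT", "b": "ACG"})

    def test_genotype_codes_and_allele_counts(self):
        table = collapse_haplotypes(
            {"i1_a0": "AAAA", "i1_a1": "AAAT", "i2_a0": "AAAA", "i2_a1": "AAAA"}
        )
        codes = table.genotype_codes()
        assert set(codes.index) == {"i1", "i2"}
        matrix = lineage.allele_count_matrix({"loc": table})
        assert matrix.loc["i2", "loc:H1"] == 2
        assert matrix.loc["i1", "loc:H2"] == 1
        assert (matrix.sum(axis=1) == 2).all()


class TestNeighborJoining:
    def test_three_sequences_unique_topology(self):
        tree = nj_tree({"a": "AAAA", "b": "AAAT", "c": "ATTT"})
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b", "c"}

    def test_identical_sequences_are_zero_distance_sisters(self):
        aln = {"a": "AAAAACCCC", "b": "AAAAACCCC", "c": "TTTTTGGGG", "d": "TTTTTAAAA"}
        labels, d = lineage._pairwise_deletion_distances(aln)
        assert d[labels.index("a"), labels.index("b")] == 0.0
        tree = nj_tree(aln)
        a = tree.find_node_with_taxon_label("a")
        b = tree.find_node_with_taxon_label("b")
        assert a.parent_node is b.parent_node

    def test_pairwise_deletion_ignores_gap_and_n_sites(self):
        aln = {"a": "A-GTN", "b": "ACGTA", "c": "TTTTT"}
        labels, d = lineage._pairwise_deletion_distances(aln)
        # a vs b: comparable sites are 1,3 (0-based 0,2,3 minus gap/N) -> A,G,T all match
        assert d[labels.index("a"), labels.index("b")] == 0.0

    def test_no_comparable_sites_is_error_naming_pair(self):
        aln = {"a": "A---", "b": "-CGT", "c": "ACGT"}
        with pytest.raises(LineageError, match="'a'.*'b'|'b'.*'a'"):
            lineage._pairwise_deletion_distances(aln)

    def test_additive_distances_recover_known_topology(self):
        """Sequences built by flipping disjoint site blocks per tree edge
        give additive p-distances; NJ must recover the generating tree."""
        length = 60
        base = "A" * length
        # tree ((a,b),(c,d),e) with per-edge private blocks
        blocks = {
            "a": range(0, 4),
            "b": range(4, 10),
            "ab": range(10, 18),
            "c": range(18, 21),
            "d": range(21, 27),
            "cd": range(27, 36),
            "e": range(36, 48),
        }

        def flip(seq, sites):
            out = list(seq)
            for s in sites:
                out[s] = "T"
            return "".join(out)

        aln = {
            "a": flip(base, list(blocks["a"]) + list(blocks["ab"])),
            "b": flip(base, list(blocks["b"]) + list(blocks["ab"])),
            "c": flip(base, list(blocks["c"]) + list(blocks["cd"])),
            "d": flip(base, list(blocks["d"]) + list(blocks["cd"])),
            "e": flip(base, list(blocks["e"])),
        }
        tree = nj_tree(aln, outgroup="e")
        tips = lambda node: {l.taxon.label for l in node.leaf_iter()}
        clades = {frozenset(tips(n)) for n in tree.preorder_node_iter() if not n.is_leaf()}
        assert frozenset({"a", "b"}) in clades
        assert frozenset({"c", "d"}) in clades


class TestGsi:
    def test_monophyletic_group_scores_exactly_one(self):
        tree = tree_from("((A,B),((C,D),(E,F)));")
        assert gsi(tree, {"A", "B"}) == 1.0
        assert gsi(tree, {"C", "D", "E", "F"}) == 1.0

    def test_non_monophyletic_group_below_one(self):
        tree = tree_from("((A,(C,B)),((D,E),F));")
        value = gsi(tree, {"A", "B"})
        assert 0.0 <= value < 1.0
        assert value == pytest.approx(gsi_node_count_oracle(tree, {"A", "B"}))

    def test_matches_node_count_oracle_on_random_trees(self):
        """Independent leaf-set-scan oracle over random topologies and
        random groups, including polytomies."""
        rng = np.random.default_rng(17)
        newicks = [
            "((A,(C,B)),((D,E),F));",
            "(((A,B),(C,(D,(E,F)))),(G,H));",
            "((A,B,C),(D,(E,F,G)));",  # polytomies
            "(((A,C),(B,G)),((D,F),(E,H)));",
        ]
        import random

        from dendropy.simulate import treesim

        for rep in range(30):
            tns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
            newicks.append(
                treesim.pure_kingman_tree(
                    taxon_namespace=tns, pop_size=1, rng=random.Random(rep)
                ).as_string(schema="newick")
            )
        for newick in newicks:
            tree = tree_from(newick)
            labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
            for _ in range(5):
                k = int(rng.integers(2, len(labels)))
                group = set(rng.choice(labels, size=k, replace=False))
                assert gsi(tree, group) == pytest.approx(
                    gsi_node_count_oracle(tree, group)
                ), (newick, sorted(group))

    def test_branch_length_invariance(self):
        with_lengths = tree_from("((A:1,(C:9,B:0.1):2):1,((D:5,E:1):1,F:1):3);")
        without = tree_from("((A,(C,B)),((D,E),F));")
        assert gsi(with_lengths, {"A", "B"}) == gsi(without, {"A", "B"})

    def test_error_cases(self):
        tree = tree_from("((A,B),(C,D));")
        with pytest.raises(LineageError):
            gsi(tree, {"A"})
        with pytest.raises(LineageError):
            gsi(tree, {"A", "B", "C", "D"})
        with pytest.raises(LineageError, match="absent"):
            gsi(tree, {"A", "Z"})

    def test_unrooted_tree_rejected(self):
        unrooted = dendropy.Tree.get(
            data="(A,B,(C,D));", schema="newick", rooting="force-unrooted"
        )
        with pytest.raises(LineageError, match="rooted"):
            gsi(unrooted, {"A", "B"})


class TestGsiTest:
    def test_monophyly_on_all_loci_hits_p_floor(self):
        # 20 individuals, group of 6: the permutation space is large
        # enough that the observed subset is never redrawn
        tips = [f"i{j}" for j in range(20)]
        clade = ",".join(tips[:6])
        rest = ",".join(tips[6:])
        trees = [tree_from(f"(({clade}),({rest}));") for _ in range(3)]
        for i, t in enumerate(trees):
            t.label = f"locus{i + 1}"
        result = gsi_test(trees, tips[:6], n_permutations=999, seed=3)
        assert result.gsi_t == 1.0
        assert (result.per_locus["gsi"] == 1.0).all()
        assert result.p_t == pytest.approx(1 / 1000)

    def test_exact_p_matches_exhaustive_enumeration(self):
        tree = tree_from("((A,(C,B)),((D,E),F));")
        group = {"A", "B", "C"}
        result = gsi_test(tree, group, method="exact")
        observed = gsi(tree, group)
        labels = ["A", "B", "C", "D", "E", "F"]
        values = [
            gsi(tree, set(combo)) for combo in itertools.combinations(labels, 3)
        ]
        expected = np.mean([v >= observed - 1e-12 for v in values])
        assert result.per_locus.loc[0, "p"] == pytest.approx(expected)
        assert result.p_t == pytest.approx(expected)
        assert result.n_permutations == 20

    def test_allele_tips_matched_by_individual_prefix(self, small_truth, small_config):
        group = [i for i in small_config.individual_ids if i.startswith("g1")]
        result = gsi_test(small_truth.gene_trees, group, n_permutations=99, seed=1)
        assert len(result.per_locus) == 4
        assert 0.0 <= result.gsi_t <= 1.0

    def test_seed_reproducibility_and_p_never_zero(self, small_truth):
        group = ["g2i0", "g2i1", "g2i2"]
        a = gsi_test(small_truth.gene_trees, group, n_permutations=199, seed=5)
        b = gsi_test(small_truth.gene_trees, group, n_permutations=199, seed=5)
        assert a.p_t == b.p_t
        assert (a.per_locus["p"] > 0).all()
        pd.testing.assert_frame_equal(a.per_locus, b.per_locus)

    def test_mean_gsi_increases_with_species_depth(self):
        """Monte-Carlo over replicate loci at three divergence depths."""
        from specdelim import syndata

        means = []
        for depth in (0.2, 1.0, 5.0):
            cfg = syndata.default_config(
                seed=19,
                n_groups=2,
                species_tree_depths=(depth,),
                n_individuals_per_group=4,
                n_loci=40,
                locus_lengths=(10,) * 40,
                ploidy=(1,) * 40,
                mutation_rate=0.0,
                landmark_mean_shapes=syndata.default_mean_shapes(2),
                feature_group_means=syndata.default_feature_params(2)[0],
            )
            truth = syndata.simulate_genetic_data(cfg)
            group = [i for i in cfg.individual_ids if i.startswith("g1")]
            values = [
                gsi(t, {f"{g}_a0" for g in group}) for t in truth.gene_trees
            ]
            means.append(np.mean(values))
        assert means[0] < means[1] < means[2]


class TestEvannoDeltaK:
    @staticmethod
    def runs_with(means, sd=1.0):
        rows = []
        for k, m in enumerate(means, start=1):
            for run, offset in enumerate((-sd / np.sqrt(2), sd / np.sqrt(2))):
                rows.append({"K": k, "run": run, "lnP": m + offset})
        return pd.DataFrame(rows)

    def test_hand_computed_second_difference(self):
        summary = self.runs_with([-1000.0, -800.0, -790.0, -788.0])
        result = evanno_delta_k(summary).set_index("K")
        # |mean(-790) - 2*mean(-800) + mean(-1000)| / 1 = 190
        assert result.loc[2, "delta_K"] == pytest.approx(190.0)
        assert result.loc[3, "delta_K"] == pytest.approx(8.0)

    def test_linear_lnp_gives_zero(self):
        summary = self.runs_with([-100.0, -90.0, -80.0, -70.0])
        result = evanno_delta_k(summary)
        np.testing.assert_allclose(result["delta_K"], 0.0, atol=1e-9)

    def test_single_k_warns_and_returns_empty(self):
        summary = self.runs_with([-100.0])
        with pytest.warns(UserWarning):
            result = evanno_delta_k(summary)
        assert result.empty

    def test_zero_sd_is_explicit_error(self):
        summary = self.runs_with([-100.0, -90.0, -80.0], sd=0.0)
        with pytest.raises(LineageError, match="zero"):
            evanno_delta_k(summary)
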