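"""Fitch lengths, tree statistics, searches, bootstrap and the ILD test."""

import random

import pytest

from helpers import (
    brute_force_fitch,
    markov_binary_characters,
    perfect_split_characters,
    random_unrooted_tree,
)
from reticulator.alignment import Alignment
from reticulator.parsimony import (
    CharacterMatrix,
    PhyloTree,
    bootstrap_support,
    exhaustive_mp,
    fitch_bounds,
    fitch_length,
    heuristic_mp,
    ild_test,
    n_unrooted_topologies,
    tree_score,
)

ABCD = ("A", "B", "C", "D")


def tree(newick, taxa):
    return PhyloTree.from_newick(newick, taxa=taxa)


class TestFitch:
    def test_single_binary_character_on_matching_tree(self):
        m = CharacterMatrix.from_binary(ABCD, ["0", "0", "1", "1"])
        assert fitch_length(tree("((A,B),(C,D));", ABCD), m) == 1

    def test_single_binary_character_on_conflicting_tree(self):
        m = CharacterMatrix.from_binary(ABCD, ["0", "0", "1", "1"])
        assert fitch_length(tree("((A,C),(B,D));", ABCD), m) == 2

    def test_all_missing_character_contributes_nothing(self):
        m = CharacterMatrix.from_binary(ABCD, ["?", "?", "?", "?"])
        assert fitch_length(tree("((A,B),(C,D));", ABCD), m) == 0

    def test_leaf_without_data_row_raises(self):
        m = CharacterMatrix.from_binary(("A", "B", "C"), ["0", "0", "1"])
        with pytest.raises(KeyError):
            fitch_length(tree("((A,B),(C,D));", ABCD), m)

    def test_matches_brute_force_enumeration(self):
        rng = random.Random(5)
        for _ in range(100):
            n = rng.randint(4, 6)
            taxa = [f"t{i}" for i in range(n)]
            t = random_unrooted_tree(taxa, rng)
            n_char = rng.randint(2, 5)
            rows = [
                "".join(rng.choice("ACGT-") for _ in range(n_char)) for _ in range(n)
            ]
            m = CharacterMatrix.from_alignment(Alignment(taxa, rows))
            assert fitch_length(t, m) == brute_force_fitch(t, m)

    def test_agrees_with_dendropy_on_dna(self):
        import dendropy
        from dendropy.model.parsimony import fitch_down_pass

        rng = random.Random(17)
        taxa = [f"t{i}" for i in range(6)]
        rows = ["".join(rng.choice("ACGT") for _ in range(30)) for _ in taxa]
        fasta = "".join(f">{t}\n{r}\n" for t, r in zip(taxa, rows))
        data = dendropy.DnaCharacterMatrix.get(data=fasta, schema="fasta")
        our_tree = random_unrooted_tree(taxa, rng)
        dtree = dendropy.Tree.get(
            data=our_tree.to_newick(), schema="newick",
            taxon_namespace=data.taxon_namespace,
        )
        score = fitch_down_pass(
            dtree.postorder_node_iter(),
            taxon_state_sets_map=data.taxon_state_sets_map(gaps_as_missing=True),
        )
        ours = fitch_length(our_tree, CharacterMatrix.from_alignment(Alignment(taxa, rows)))
        assert ours == score

    def test_taxon_relabeling_preserves_scores(self):
        rng = random.Random(3)
        taxa = [f"t{i}" for i in range(6)]
        rows = ["".join(rng.choice("01") for _ in range(12)) for _ in taxa]
        m = CharacterMatrix.from_binary(taxa, rows)
        t = random_unrooted_tree(taxa, rng)
        length = fitch_length(t, m)
        perm = {"t0": "z9", "t1": "z1", "t2": "z5", "t3": "z3", "t4": "z0", "t5": "z2"}
        m2 = CharacterMatrix.from_binary([perm[x] for x in taxa], rows)
        assert fitch_length(t.relabel(perm), m2) == length
        assert tree_score(length, m2).ci == tree_score(length, m).ci


class TestBoundsAndIndices:
    @pytest.mark.parametrize(
        "states, expected",
        [
            ("AACCC", (1, 2)),
            ("AAA", (0, 0)),
            ("ACGT", (3, 3)),
        ],
    )
    def test_step_bounds(self, states, expected):
        taxa = [f"t{i}" for i in range(len(states))]
        m = CharacterMatrix.from_alignment(Alignment(taxa, list(states)))
        assert fitch_bounds(m) == [expected]

    def test_indices_stay_in_declared_ranges(self):
        rng = random.Random(8)
        for _ in range(30):
            n = rng.randint(4, 7)
            taxa = [f"t{i}" for i in range(n)]
            rows = ["".join(rng.choice("01?") for _ in range(10)) for _ in taxa]
            m = CharacterMatrix.from_binary(taxa, rows)
            result = heuristic_mp(m, n_random_addition=2, seed=1)
            bounds = fitch_bounds(m)
            assert result.length >= sum(b[0] for b in bounds)
            assert result.length <= sum(b[0] + b[1] for b in bounds)
            if result.length > 0:
                assert 0 < result.score.ci <= 1
            assert 0 <= result.score.ri <= 1


class TestExhaustive:
    def test_compatible_characters_give_unique_tree_without_homoplasy(self):
        m = CharacterMatrix.from_binary(ABCD, ["000", "000", "111", "111"])
        result = exhaustive_mp(m)
        assert len(result.trees) == 1
        assert result.trees[0].splits() == {frozenset({"C", "D"})}
        assert result.score.ci == 1.0

    def test_invariant_matrix_ties_all_topologies(self):
        taxa = [f"t{i}" for i in range(5)]
        m = CharacterMatrix.from_binary(taxa, ["0000"] * 5)
        result = exhaustive_mp(m)
        assert result.length == 0
        assert len(result.trees) == n_unrooted_topologies(5) == 15

    def test_out_of_range_taxon_counts_rejected(self):
        m = CharacterMatrix.from_binary(("a", "b", "c"), ["0", "1", "0"])
        with pytest.raises(ValueError):
            exhaustive_mp(m)


class TestHeuristic:
    def test_finds_exhaustive_optimum_on_random_matrices(self):
        rng = random.Random(21)
        for trial in range(15):
            taxa = [f"t{i}" for i in range(6)]
            rows = ["".join(rng.choice("01") for _ in range(15)) for _ in taxa]
            m = CharacterMatrix.from_binary(taxa, rows)
            assert (
                heuristic_mp(m, n_random_addition=5, seed=trial).length
                == exhaustive_mp(m).length
            )

    def test_duplicated_taxon_does_not_change_best_length(self):
        rng = random.Random(4)
        taxa = [f"t{i}" for i in range(6)]
        rows = ["".join(rng.choice("01") for _ in range(15)) for _ in taxa]
        base = heuristic_mp(
            CharacterMatrix.from_binary(taxa, rows), n_random_addition=5, seed=0
        )
        dup = heuristic_mp(
            CharacterMatrix.from_binary(taxa + ["t0b"], rows + [rows[0]]),
            n_random_addition=5,
            seed=0,
        )
        assert dup.length == base.length

    def test_invariant_matrix_scores_zero(self):
        taxa = [f"t{i}" for i in range(5)]
        m = CharacterMatrix.from_binary(taxa, ["0000"] * 5)
        assert heuristic_mp(m, n_random_addition=1, seed=0).length == 0

    def test_deterministic_given_seed(self):
        rng = random.Random(9)
        taxa = [f"t{i}" for i in range(7)]
        rows = ["".join(rng.choice("01") for _ in range(20)) for _ in taxa]
        m = CharacterMatrix.from_binary(taxa, rows)
        a = heuristic_mp(m, n_random_addition=3, seed=42)
        b = heuristic_mp(m, n_random_addition=3, seed=42)
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]


class TestBootstrap:
    def test_single_character_split_gets_full_support(self):
        taxa = [f"t{i}" for i in range(5)]
        m = CharacterMatrix.from_binary(taxa, ["0", "0", "0", "1", "1"])
        support = bootstrap_support(m, n_reps=50, seed=0)
        assert support[frozenset({"t3", "t4"})] == 1.0

    def test_unanimous_characters_give_near_certain_support(self):
        m = CharacterMatrix.from_binary(ABCD, ["0" * 20, "0" * 20, "1" * 20, "1" * 20])
        support = bootstrap_support(m, n_reps=200, seed=1)
        assert support[frozenset({"C", "D"})] >= 0.99

    def test_evenly_conflicting_characters_split_support(self):
        # 10 characters for AB|CD against 10 for AC|BD
        rows = ["0" * 10 + "0" * 10, "0" * 10 + "1" * 10, "1" * 10 + "0" * 10,
                "1" * 10 + "1" * 10]
        m = CharacterMatrix.from_binary(ABCD, rows)
        support = bootstrap_support(m, n_reps=400, seed=2)
        ab_cd = support.get(frozenset({"C", "D"}), 0.0)
        assert 0.35 <= ab_cd <= 0.65


class TestILD:
    def test_identical_partitions_are_never_significant(self):
        rng = random.Random(12)
        taxa = [f"t{i}" for i in range(6)]
        t = random_unrooted_tree(taxa, rng)
        m = markov_binary_characters(t, 15, rng, 0.25)
        result = ild_test(m, m, n_reps=99, seed=0)
        assert result.d_obs == 0
        assert result.p_value > 0.5

    def test_p_value_invariant_to_partition_order(self):
        rng = random.Random(13)
        taxa = [f"t{i}" for i in range(6)]
        t = random_unrooted_tree(taxa, rng)
        p1 = markov_binary_characters(t, 12, rng, 0.3)
        p2 = markov_binary_characters(t, 17, rng, 0.3)
        a = ild_test(p1, p2, n_reps=99, seed=5)
        b = ild_test(p2, p1, n_reps=99, seed=5)
        assert a.p_value == b.p_value
        assert a.d_obs == b.d_obs

    def test_conflicting_partitions_detected(self):
        taxa = [f"t{i}" for i in range(6)]
        t1 = tree("((t0,t1),((t2,t3),(t4,t5)));", taxa)
        t2 = tree("((t0,t2),((t1,t4),(t3,t5)));", taxa)
        assert not (t1.splits() & t2.splits())
        rng = random.Random(1)
        p1 = perfect_split_characters(t1, 30, rng)
        p2 = perfect_split_characters(t2, 30, rng)
        assert ild_test(p1, p2, n_reps=199, seed=3).p_value <= 0.05

    def test_mismatched_taxon_sets_rejected(self):
        m1 = CharacterMatrix.from_binary(ABCD, ["0", "0", "1", "1"])
        m2 = CharacterMatrix.from_binary(("A", "B", "C", "E"), ["0", "0", "1", "1"])
        with pytest.raises(ValueError):
            ild_test(m1, m2)


class TestTreeIO:
    def test_newick_roundtrip_preserves_topology(self):
        rng = random.Random(2)
        taxa = [f"t{i}" for i in range(8)]
        t = random_unrooted_tree(taxa, rng)
        again = PhyloTree.from_newick(t.to_newick(), taxa=taxa)
        assert again.splits() == t.splits()

    def test_rooted_newick_is_smoothed(self):
        t = PhyloTree.from_newick("(((A,B),C),D);", taxa=ABCD)
        assert t.splits() == {frozenset({"A", "B"})} or t.splits() == {
            frozenset({"C", "D"})
        }
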