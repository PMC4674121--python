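"""Random addition, TBR rearrangement, heuristic search, consensus."""

import random

import pytest

from parsimorph.matrix import CharacterMatrix, StateSet
from parsimorph.parsimony_core import fitch_length, min_steps
from parsimorph.tree import Tree
from parsimorph.tree_search import (
    SearchConfig,
    collapse_ambiguous_edges,
    enumerate_unrooted_topologies,
    exhaustive_search,
    heuristic_search,
    random_addition_tree,
    strict_consensus,
    tbr_neighbors,
)

from conftest import naive_tbr_neighborhood, random_matrix, random_topology


class TestRandomAddition:
    def test_three_taxa_gives_the_single_topology(self):
        m = random_matrix(random.Random(0), 3, 2)
        t = random_addition_tree(m, 0)
        assert t.leaf_set() == {"T0", "T1", "T2"}

    def test_perfect_matrix_already_attains_minimum(self):
        """On a compatible (homoplasy-free) matrix the greedy addition
        tree reaches the analytic minimum length Σ min_steps."""
        rng = random.Random(1)
        for trial in range(8):
            labels = [f"T{i}" for i in range(7)]
            tree = random_topology(rng, labels)
            rows = {lab: [] for lab in labels}
            for side in sorted(tree.bipartitions(), key=sorted):
                for lab in labels:
                    rows[lab].append(StateSet.of(1 if lab in side else 0))
            m = CharacterMatrix(labels, [rows[lab] for lab in labels])
            added = random_addition_tree(m, rng.randrange(2**31))
            analytic = sum(min_steps(m.column(i)) for i in range(m.n_chars))
            assert fitch_length(added, m).total_length == analytic

    def test_fixed_seed_is_deterministic(self):
        m = random_matrix(random.Random(2), 8, 10)
        a = random_addition_tree(m, 123)
        b = random_addition_tree(m, 123)
        assert a.topology_key() == b.topology_key()


class TestTbrNeighbors:
    def test_quartet_neighbors_are_the_two_other_topologies(self):
        t = Tree.from_nested((("A", "B"), ("C", "D")))
        keys = {n.topology_key() for n in tbr_neighbors(t)}
        all_keys = {
            x.topology_key()
            for x in enumerate_unrooted_topologies(["A", "B", "C", "D"])
        }
        assert keys == all_keys - {t.topology_key()}
        assert len(keys) == 2

    def test_five_leaf_neighborhood_matches_definition_oracle(self):
        """Independent fragment-restriction oracle over all 15 topologies
        (12 of the 14 alternatives are one TBR move away; the two trees
        sharing no compatible 4-leaf restriction are not)."""
        t = Tree.from_nested(((("A", "B"), "C"), ("D", "E")))
        keys = {n.topology_key() for n in tbr_neighbors(t)}
        assert keys == naive_tbr_neighborhood(t)
        assert len(keys) == 12

    def test_random_trees_match_definition_oracle(self):
        rng = random.Random(9)
        for n in (6, 7):
            labels = [f"T{i}" for i in range(n)]
            t = random_topology(rng, labels)
            keys = {x.topology_key() for x in tbr_neighbors(t)}
            assert keys == naive_tbr_neighborhood(t)
            assert t.topology_key() not in keys


class TestHeuristicSearch:
    def test_matches_exhaustive_search_on_random_matrices(self):
        rng = random.Random(21)
        for trial in range(12):
            n = rng.randint(5, 6)
            m = random_matrix(rng, n, rng.randint(4, 8), p_missing=0.1)
            best, trees = exhaustive_search(m)
            res = heuristic_search(
                m, SearchConfig(n_addition_replicates=8, seed=trial)
            )
            assert res.best_length == best
            assert {t.topology_key() for t in res.best_trees} == {
                t.topology_key() for t in trees
            }

    def test_every_retained_tree_rescored_gives_best_length(self):
        rng = random.Random(23)
        m = random_matrix(rng, 7, 8)
        res = heuristic_search(m, SearchConfig(n_addition_replicates=10, seed=5))
        for t in res.best_trees:
            assert fitch_length(t, m).total_length == res.best_length

    def test_best_length_monotone_in_replicates(self):
        rng = random.Random(29)
        m = random_matrix(rng, 9, 12)
        lengths = [
            heuristic_search(
                m, SearchConfig(n_addition_replicates=reps, seed=1)
            ).best_length
            for reps in (1, 3, 10)
        ]
        assert lengths[0] >= lengths[1] >= lengths[2]

    def test_recovers_generating_tree_from_homoplasy_free_matrix(self):
        """A perfect matrix (one binary character per split of a known
        tree) has that tree as its unique MPT; the search must find it
        at length = number of splits."""
        rng = random.Random(37)
        for trial in range(5):
            n = 8
            labels = [f"T{i}" for i in range(n)]
            tree = random_topology(rng, labels)
            splits = sorted(tree.bipartitions(), key=sorted)
            rows = {lab: [] for lab in labels}
            for side in splits:
                for lab in labels:
                    rows[lab].append(StateSet.of(1 if lab in side else 0))
            m = CharacterMatrix(labels, [rows[lab] for lab in labels])
            res = heuristic_search(
                m, SearchConfig(n_addition_replicates=5, seed=trial)
            )
            assert res.best_length == len(splits)
            assert [t.topology_key() for t in res.best_trees] == [
                tree.topology_key()
            ]

    def test_search_log_records_seed_and_replicates(self):
        m = random_matrix(random.Random(31), 6, 5)
        res = heuristic_search(m, SearchConfig(n_addition_replicates=2, seed=77))
        assert res.log[0]["seed"] == 77
        assert len([e for e in res.log if "replicate" in e]) == 2


class TestStrictConsensus:
    def test_identical_trees_return_same_topology(self):
        t = Tree.from_nested(((("A", "B"), "C"), ("D", "E")))
        assert strict_consensus([t, t.copy()]).same_unrooted(t)

    def test_conflict_collapses_to_polytomy_keeping_shared_clade(self):
        t1 = Tree.from_nested((("A", "B"), "C", ("D", "E")))
        t2 = Tree.from_nested((("A", "C"), "B", ("D", "E")))
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == frozenset({frozenset({"D", "E"})})

    def test_differing_leaf_sets_rejected(self):
        t1 = Tree.from_nested((("A", "B"), ("C", "D")))
        t2 = Tree.from_nested((("A", "B"), ("C", "E")))
        with pytest.raises(ValueError):
            strict_consensus([t1, t2])


class TestCollapse:
    def test_unsupported_branch_is_collapsed(self):
        # only character splits {A,B} from {C,D,E}; the (D,E) branch has
        # minimum length zero and should collapse
        taxa = ["A", "B", "C", "D", "E"]
        m = CharacterMatrix(
            taxa,
            [[StateSet.of(1)], [StateSet.of(1)], [StateSet.of(0)],
             [StateSet.of(0)], [StateSet.of(0)]],
        )
        t = Tree.from_nested(((("A", "B"), "C"), ("D", "E")))
        collapsed = collapse_ambiguous_edges(t, m)
        # the {A,B} | {C,D,E} split survives (canonical side excludes "A")
        assert collapsed.bipartitions() == frozenset({frozenset({"C", "D", "E"})})
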