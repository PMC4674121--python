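"""Fitch/Sankoff scoring, per-character bounds, and homoplasy indices."""

import random

import pytest

from parsimorph.matrix import CharacterMatrix, StateSet
from parsimorph.parsimony_core import (
    PackedMatrix,
    fitch_length,
    homoplasy_indices,
    max_steps,
    min_steps,
    per_character_lengths,
)
from parsimorph.tree import Tree
from parsimorph.tree_search import (
    _score,
    _tree_to_adj,
    enumerate_unrooted_topologies,
    root_on_outgroup,
)

from conftest import brute_force_length, random_matrix, random_topology


def column(*cells):
    out = []
    for c in cells:
        if c == "?":
            out.append(StateSet.missing(frozenset({0, 1, 2, 3})))
        elif isinstance(c, tuple):
            out.append(StateSet.of(*c))
        else:
            out.append(StateSet.of(c))
    return out


class TestFitchLength:
    def test_constant_matrix_has_zero_length(self):
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [[StateSet.of(0)] * 3 for _ in range(4)],
        )
        t = Tree.from_nested((("A", "B"), ("C", "D")))
        assert fitch_length(t, m).total_length == 0

    def test_quartet_with_conflicting_character_needs_two_steps(self):
        """A=0,B=1,C=0,D=1 on ((A,B),(C,D)): both internal labelings
        force 2 changes (verified by brute force over all assignments)."""
        m = CharacterMatrix(
            ["A", "B", "C", "D"], [[c] for c in column(0, 1, 0, 1)]
        )
        t = Tree.from_nested((("A", "B"), ("C", "D")))
        assert brute_force_length(t, m) == 2
        assert fitch_length(t, m).total_length == 2

    def test_leaf_taxon_mismatch_reports_difference(self):
        m = CharacterMatrix(["A", "B", "C"], [[StateSet.of(0)]] * 3)
        t = Tree.from_nested((("A", "B"), "X"))
        with pytest.raises(ValueError, match="X"):
            fitch_length(t, m)

    def test_matches_exhaustive_labeling_oracle(self):
        """Sankoff and packed-Fitch lengths both equal brute-force
        minimisation over internal labelings, on random instances with
        missing and polymorphic cells and random (binary) topologies."""
        rng = random.Random(7)
        for _ in range(60):
            n = rng.randint(4, 7)
            labels = [f"T{i}" for i in range(n)]
            m = random_matrix(
                rng, n, rng.randint(1, 4), n_states=rng.randint(2, 3),
                p_missing=0.15, p_poly=0.1,
            )
            t = random_topology(rng, labels)
            expected = brute_force_length(t, m)
            assert fitch_length(t, m).total_length == expected
            packed = PackedMatrix.from_character_matrix(m)
            assert _score(_tree_to_adj(t, m.taxa), packed) == expected

    def test_exact_on_polytomies(self):
        """Sankoff scoring of multifurcating trees agrees with brute force."""
        rng = random.Random(11)
        for _ in range(30):
            n = rng.randint(4, 6)
            m = random_matrix(rng, n, 3, n_states=3, p_missing=0.2, p_poly=0.1)
            # build a random polytomous tree by collapsing a binary one
            t = random_topology(rng, [f"T{i}" for i in range(n)])
            for node in list(t.postorder()):
                if (
                    node.parent is not None
                    and not node.is_leaf
                    and rng.random() < 0.5
                ):
                    parent = node.parent
                    parent.children.remove(node)
                    for ch in node.children:
                        parent.add(ch)
            assert fitch_length(t, m).total_length == brute_force_length(t, m)

    def test_root_placement_is_irrelevant(self):
        rng = random.Random(3)
        for _ in range(20):
            n = rng.randint(4, 7)
            m = random_matrix(rng, n, 4, p_missing=0.1)
            t = random_topology(rng, [f"T{i}" for i in range(n)])
            base = fitch_length(t, m).total_length
            for leaf in m.taxa[:3]:
                rerooted = root_on_outgroup(t, [leaf], strict=True)
                assert fitch_length(rerooted, m).total_length == base

    def test_constant_character_never_changes_length(self):
        rng = random.Random(5)
        m = random_matrix(rng, 6, 5)
        t = random_topology(rng, m.taxa)
        base = fitch_length(t, m).total_length
        extended = CharacterMatrix(
            m.taxa, [row + [StateSet.of(1)] for row in m.rows]
        )
        assert fitch_length(t, extended).total_length == base


class TestStepBounds:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            (column(0, 1, 2), 2),
            (column(0, 0, 0), 0),
            (column(0, 1, (0, 1)), 1),  # resolving {01} to either saves a step
            (column("?", "?", 1), 0),
        ],
    )
    def test_min_steps(self, cells, expected):
        assert min_steps(cells) == expected

    def test_min_steps_polymorphic_matches_resolution_brute_force(self):
        """{0},{1},{0,1}: minimum over resolutions of (#states - 1)."""
        from itertools import product

        best = min(
            len({a, b, c}) - 1
            for a, b, c in product([0], [1], [0, 1])
        )
        assert min_steps(column(0, 1, (0, 1))) == best == 1

    @pytest.mark.parametrize(
        "cells,expected",
        [
            (column(0, 0, 0, 1, 1), 2),
            (column(0, 0, 0), 0),
            (column(0, 1, 2, 3), 3),
        ],
    )
    def test_max_steps(self, cells, expected):
        assert max_steps(cells) == expected

    @pytest.mark.parametrize(
        "cells", [column(0, 0, 0, 1, 1), column(0, 1, 2, 3), column(0, 1, 1, 2, 2)]
    )
    def test_max_steps_matches_worst_tree_by_enumeration(self, cells):
        """The closed form equals the maximum Fitch length over every
        unrooted topology of the right size."""
        n = len(cells)
        taxa = [f"T{i}" for i in range(n)]
        m = CharacterMatrix(taxa, [[c] for c in cells])
        worst = max(
            fitch_length(t, m).total_length
            for t in enumerate_unrooted_topologies(taxa)
        )
        assert max_steps(cells) == worst


class TestHomoplasyIndices:
    def test_perfect_matrix_has_ci_one(self):
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [
                column(1, 0),
                column(1, 0),
                column(0, 1),
                column(0, 1),
            ],
        )
        t = Tree.from_nested((("A", "B"), ("C", "D")))
        ci, ri = homoplasy_indices(t, m)
        assert ci == 1.0 and ri == 1.0

    def test_zero_length_convention(self):
        m = CharacterMatrix(["A", "B", "C"], [[StateSet.of(2)]] * 3)
        t = Tree.from_nested((("A", "B"), "C"))
        ci, ri = homoplasy_indices(t, m)
        assert (ci, ri) == (1.0, 1.0)

    def test_matches_hand_summed_toy_example(self):
        """5-taxon, 3-character toy: CI and RI from independently summed
        per-character min/max/observed steps."""
        taxa = ["A", "B", "C", "D", "E"]
        cols = [
            column(0, 0, 1, 1, 1),
            column(0, 1, 0, 1, 1),
            column(0, 0, 0, 2, 2),
        ]
        m = CharacterMatrix(taxa, [list(r) for r in zip(*cols)])
        t = Tree.from_nested(((("A", "B"), "C"), ("D", "E")))
        obs = [int(x) for x in per_character_lengths(t, m)]
        mins = [min_steps(c) for c in cols]
        maxs = [max_steps(c) for c in cols]
        # independent spreadsheet-style sums
        assert obs == [1, 2, 1]
        L, smin, smax = sum(obs), sum(mins), sum(maxs)
        ci, ri = homoplasy_indices(t, m)
        assert ci == pytest.approx(smin / L)
        assert ri == pytest.approx((smax - L) / (smax - smin))

    def test_excluding_uninformative_characters(self):
        taxa = ["A", "B", "C", "D"]
        homoplastic = column(0, 1, 0, 1)  # 2 steps on this tree, min 1
        autapomorphy = column(0, 0, 0, 1)  # min == max == 1: uninformative
        constant = column(2, 2, 2, 2)
        m = CharacterMatrix(
            taxa, [list(r) for r in zip(homoplastic, autapomorphy, constant)]
        )
        t = Tree.from_nested((("A", "B"), ("C", "D")))
        ci_all, _ = homoplasy_indices(t, m, include_uninformative=True)
        ci_inf, _ = homoplasy_indices(t, m, include_uninformative=False)
        assert ci_all == pytest.approx((1 + 1 + 0) / (2 + 1 + 0))
        assert ci_inf == pytest.approx(1 / 2)

    def test_ci_does_not_decrease_when_adding_clean_character(self):
        rng = random.Random(13)
        for _ in range(10):
            m = random_matrix(rng, 6, 4)
            t = random_topology(rng, m.taxa)
            ci0, _ = homoplasy_indices(t, m)
            # a character with a single change, consistent with any tree
            split_leaf = m.taxa[0]
            clean = [
                StateSet.of(1 if tx == split_leaf else 0) for tx in m.taxa
            ]
            m2 = CharacterMatrix(
                m.taxa, [row + [c] for row, c in zip(m.rows, clean)]
            )
            ci1, _ = homoplasy_indices(t, m2)
            assert ci1 >= ci0 - 1e-12

    def test_indices_bounded(self):
        rng = random.Random(17)
        for _ in range(25):
            m = random_matrix(rng, rng.randint(4, 7), 5, p_missing=0.1)
            t = random_topology(rng, m.taxa)
            score = fitch_length(t, m)
            if score.total_length > 0:
                assert 0.0 < score.ci <= 1.0
                assert 0.0 <= score.ri <= 1.0
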