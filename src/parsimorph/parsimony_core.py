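"""Parsimony scoring of trees on unordered multistate characters.

Two scoring engines are provided:

* :func:`fitch_length` — a vectorised unit-cost Sankoff dynamic
  programme.  It is exact on arbitrary (multifurcating) trees with
  set-valued leaves: a polymorphic or missing cell contributes zero
  internal cost for any one of its candidate states.
* :class:`PackedMatrix` plus the ``fitch_*`` bit-twiddling helpers — a
  fast binary-tree Fitch pass over the whole matrix at once, with each
  character's candidate-state set packed into a fixed-width bit field
  of one large Python integer.  This is the engine the heuristic tree
  search uses; the two engines are cross-checked in the test suite.

Homoplasy summaries follow the classical definitions: the consistency
index CI = (Σ m_i)/L and the retention index RI = (Σ g_i − L)/(Σ g_i −
Σ m_i), where m_i and g_i are the best- and worst-case tree lengths of
character i and L the observed tree length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .matrix import CharacterMatrix, StateSet, _norm_label
from .tree import Tree

_BIG = 1 << 20  # effectively infinite cost for disallowed leaf states


@dataclass(frozen=True)
class ParsimonyScore:
    total_length: int
    per_char_lengths: tuple[int, ...]
    ci: float
    ri: float


# ---------------------------------------------------------------------------
# General scoring (exact on polytomies) — vectorised Sankoff
# ---------------------------------------------------------------------------


def _check_leaves(tree: Tree, matrix: CharacterMatrix) -> None:
    tree_leaves = tree.leaf_set()
    matrix_taxa = frozenset(_norm_label(t) for t in matrix.taxa)
    if tree_leaves != matrix_taxa:
        only_tree = sorted(tree_leaves - matrix_taxa)
        only_matrix = sorted(matrix_taxa - tree_leaves)
        raise ValueError(
            "tree leaves and matrix taxa differ; "
            f"only in tree: {only_tree}; only in matrix: {only_matrix}"
        )


def per_character_lengths(tree: Tree, matrix: CharacterMatrix) -> np.ndarray:
    """Minimum number of state changes per character on ``tree``."""
    _check_leaves(tree, matrix)
    symbols = sorted(
        {s for row in matrix.rows for cell in row for s in cell.states}
    )
    index = {s: i for i, s in enumerate(symbols)}
    k = len(symbols)
    n = matrix.n_chars

    leaf_cost: dict[str, np.ndarray] = {}
    for taxon, row in zip(matrix.taxa, matrix.rows):
        cost = np.full((n, k), _BIG, dtype=np.int64)
        for ci, cell in enumerate(row):
            for s in cell.states:
                cost[ci, index[s]] = 0
        leaf_cost[_norm_label(taxon)] = cost

    node_cost: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            node_cost[id(node)] = leaf_cost[_norm_label(node.label or "")]
        else:
            total = np.zeros((n, k), dtype=np.int64)
            for child in node.children:
                c = node_cost.pop(id(child))
                contrib = np.minimum(c, c.min(axis=1, keepdims=True) + 1)
                total += contrib
            node_cost[id(node)] = total
    root_cost = node_cost[id(tree.root)]
    return root_cost.min(axis=1)


def fitch_length(
    tree: Tree, matrix: CharacterMatrix, include_uninformative: bool = True
) -> ParsimonyScore:
    """Score a tree: minimum total changes plus CI/RI summaries."""
    per_char = per_character_lengths(tree, matrix)
    total = int(per_char.sum())
    ci, ri = homoplasy_indices(
        tree, matrix, include_uninformative=include_uninformative, _per_char=per_char
    )
    return ParsimonyScore(
        total_length=total,
        per_char_lengths=tuple(int(x) for x in per_char),
        ci=ci,
        ri=ri,
    )


# ---------------------------------------------------------------------------
# Per-character bounds and homoplasy indices
# ---------------------------------------------------------------------------


def min_steps(column: Sequence[StateSet]) -> int:
    """Best-case (fewest possible) changes for one character.

    Equals (size of the smallest state subset hitting every scoreable
    cell) − 1: on a best-case tree each extra required state costs one
    origin.  Missing cells are compatible with anything.
    """
    sets = [cell.states for cell in column if not cell.is_missing]
    if not sets:
        return 0
    universe = sorted(frozenset().union(*sets))
    for size in range(1, len(universe) + 1):
        for combo in combinations(universe, size):
            chosen = set(combo)
            if all(chosen & s for s in sets):
                return size - 1
    return len(universe) - 1  # unreachable


def max_steps(column: Sequence[StateSet]) -> int:
    """Worst-case changes for one character over all trees.

    (number of scoreable cells) − (largest achievable single-state
    frequency); polymorphic cells are resolved in favour of the
    dominant state.
    """
    sets = [cell.states for cell in column if not cell.is_missing]
    if not sets:
        return 0
    universe = frozenset().union(*sets)
    best = max(sum(1 for s in sets if state in s) for state in universe)
    return len(sets) - best


def is_parsimony_informative(column: Sequence[StateSet]) -> bool:
    """A character is informative iff its best and worst cases differ."""
    return max_steps(column) > min_steps(column)


def homoplasy_indices(
    tree: Tree,
    matrix: CharacterMatrix,
    include_uninformative: bool = True,
    _per_char: np.ndarray | None = None,
) -> tuple[float, float]:
    """Ensemble consistency and retention indices of ``matrix`` on ``tree``.

    With ``include_uninformative=False``, constant and autapomorphic
    characters (min == max steps) are dropped from the sums.  When the
    observed length is zero, both indices are 1.0 by convention.
    """
    if _per_char is None:
        _per_char = per_character_lengths(tree, matrix)
    mins = np.array([min_steps(matrix.column(i)) for i in range(matrix.n_chars)])
    maxs = np.array([max_steps(matrix.column(i)) for i in range(matrix.n_chars)])
    keep = np.ones(matrix.n_chars, dtype=bool)
    if not include_uninformative:
        keep = maxs > mins
    L = int(_per_char[keep].sum())
    sum_min = int(mins[keep].sum())
    sum_max = int(maxs[keep].sum())
    ci = 1.0 if L == 0 else sum_min / L
    ri = 1.0 if sum_max == sum_min else (sum_max - L) / (sum_max - sum_min)
    return float(ci), float(ri)


def character_step_table(tree: Tree, matrix: CharacterMatrix):
    """Per-character TSV-ready table: index, min, max, observed steps."""
    import pandas as pd

    per_char = per_character_lengths(tree, matrix)
    return pd.DataFrame(
        {
            "character": np.arange(1, matrix.n_chars + 1),
            "min_steps": [min_steps(matrix.column(i)) for i in range(matrix.n_chars)],
            "max_steps": [max_steps(matrix.column(i)) for i in range(matrix.n_chars)],
            "observed_steps": per_char.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# Packed fast path (binary trees) used by the heuristic search
# ---------------------------------------------------------------------------


class PackedMatrix:
    """The whole matrix packed into one big integer per taxon.

    Each character occupies a ``width``-bit field (one bit per symbol);
    a set bit means "this state is a candidate here".  A binary Fitch
    combine over all characters is then a handful of integer operations
    regardless of character count.
    """

    def __init__(self, taxa: Sequence[str], cell_bits: list[list[int]], width: int):
        self.taxa = list(taxa)
        self.cell_bits = cell_bits  # per taxon, per character small bitmask
        self.width = width
        self.n_chars = len(cell_bits[0]) if cell_bits else 0
        self.cellmask = (1 << width) - 1
        low = 0
        for c in range(self.n_chars):
            low |= 1 << (c * width)
        self.lowmask = low
        self.rows = [self._pack(row) for row in cell_bits]

    @classmethod
    def from_character_matrix(cls, matrix: CharacterMatrix) -> "PackedMatrix":
        symbols = sorted(
            {s for row in matrix.rows for cell in row for s in cell.states}
        )
        index = {s: i for i, s in enumerate(symbols)}
        width = max(len(symbols), 1)
        cell_bits = [
            [
                sum(1 << index[s] for s in cell.states)
                for cell in row
            ]
            for row in matrix.rows
        ]
        return cls(matrix.taxa, cell_bits, width)

    def _pack(self, bits_row: Sequence[int]) -> int:
        packed = 0
        for c, bits in enumerate(bits_row):
            packed |= bits << (c * self.width)
        return packed

    def resample_columns(self, indices: Sequence[int]) -> "PackedMatrix":
        """New matrix built from the given character columns (bootstrap)."""
        cell_bits = [[row[i] for i in indices] for row in self.cell_bits]
        return PackedMatrix(self.taxa, cell_bits, self.width)

    # -- Fitch primitives ----------------------------------------------
    def combine(self, a: int, b: int) -> tuple[int, int]:
        """Fitch combine of two candidate-set vectors.

        Returns (combined vector, number of characters forced to change).
        """
        inter = a & b
        fold = inter
        for i in range(1, self.width):
            fold |= inter >> i
        zero = (fold & self.lowmask) ^ self.lowmask
        cost = zero.bit_count()
        if cost:
            return inter | ((a | b) & (zero * self.cellmask)), cost
        return inter, 0

    def join_cost(self, a: int, b: int) -> int:
        """Changes forced by joining two candidate-set vectors with an edge."""
        inter = a & b
        fold = inter
        for i in range(1, self.width):
            fold |= inter >> i
        return ((fold & self.lowmask) ^ self.lowmask).bit_count()
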