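"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own algorithms:
parsimony lengths by exhaustive enumeration of internal labelings, TBR
neighborhoods by a definition-level fragment-restriction check, and
squared-change parsimony by generic numeric minimisation.
"""

from __future__ import annotations

import random
from itertools import product

import numpy as np
import pytest

from parsimorph.matrix import CharacterMatrix, StateSet
from parsimorph.tree import Tree
from parsimorph.tree_search import enumerate_unrooted_topologies
from parsimorph.synthetic_data import (
    synthetic_study_matrix,
    synthetic_study_traits,
)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study_matrix() -> CharacterMatrix:
    """Synthetic stand-in for the 21 x 43 physeteroid character matrix."""
    return synthetic_study_matrix()


@pytest.fixture(scope="session")
def study_traits():
    return synthetic_study_traits()


def random_matrix(
    rng: random.Random,
    n_taxa: int,
    n_chars: int,
    n_states: int = 3,
    p_missing: float = 0.0,
    p_poly: float = 0.0,
) -> CharacterMatrix:
    taxa = [f"T{i}" for i in range(n_taxa)]
    full = frozenset(range(n_states))
    rows = []
    for _ in taxa:
        row = []
        for _ in range(n_chars):
            u = rng.random()
            if u < p_missing:
                row.append(StateSet.missing(full))
            elif u < p_missing + p_poly and n_states > 1:
                pair = rng.sample(range(n_states), 2)
                row.append(StateSet.of(*pair))
            else:
                row.append(StateSet.of(rng.randrange(n_states)))
        rows.append(row)
    return CharacterMatrix(taxa, rows)


def random_topology(rng: random.Random, labels: list[str]) -> Tree:
    """Uniform-ish random unrooted binary topology via random edge insertion."""
    n = len(labels)
    # build by inserting leaves on random edges of a growing adjacency
    adj = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    nxt = n + 1
    for leaf in range(3, n):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.randrange(len(edges))]
        w = nxt
        nxt += 1
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].append(w)
        adj[v].append(w)
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
    from parsimorph.tree_search import _adj_to_tree

    return _adj_to_tree(adj, labels)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Minimum changes by exhaustive enumeration of internal labelings."""
    symbols = sorted(
        {s for row in matrix.rows for cell in row for s in cell.states}
    )
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    cell_of = {}
    for node in nodes:
        if node.is_leaf:
            cell_of[id(node)] = matrix.cell(node.label, 0)  # placeholder
    total = 0
    for ci in range(matrix.n_chars):
        for node in nodes:
            if node.is_leaf:
                cell_of[id(node)] = matrix.cell(node.label, ci)
        best = None
        for assign in product(symbols, repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            cost = 0
            for node in nodes:
                if node.parent is None:
                    continue
                p = state[id(node.parent)]
                if node.is_leaf:
                    if p not in cell_of[id(node)]:
                        cost += 1
                elif state[id(node)] != p:
                    cost += 1
            if best is None or cost < best:
                best = cost
        total += best
    return total


def _restricted_splits(tree: Tree, subset: frozenset[str]) -> frozenset:
    out = set()
    for split in tree.bipartitions():
        leaves = tree.leaf_set()
        for side in (split, leaves - split):
            r = frozenset(side) & subset
            if 2 <= len(r) <= len(subset) - 2:
                out.add(min(r, frozenset(subset - r), key=sorted))
    return frozenset(out)


def is_tbr_neighbor(t1: Tree, t2: Tree) -> bool:
    """Definition-level check: one TBR move cuts an edge of t1 into leaf
    fragments (X, Y); the move preserves the induced subtree on each
    fragment, and in the result X and Y are again separated by a single
    edge."""
    leaves = t1.leaf_set()
    if t1.bipartitions() == t2.bipartitions():
        return False
    candidate_sides = set(t1.bipartitions())
    for leaf in leaves:
        candidate_sides.add(frozenset({leaf}))
    for x in candidate_sides:
        y = leaves - x
        # X must be edge-separable in t2 as well
        if len(x) >= 2 and len(y) >= 2 and x not in t2.bipartitions() and y not in t2.bipartitions():
            continue
        if _restricted_splits(t1, x) != _restricted_splits(t2, x):
            continue
        if _restricted_splits(t1, y) != _restricted_splits(t2, y):
            continue
        return True
    return False


def naive_tbr_neighborhood(tree: Tree) -> set:
    """All topologies (by key) at TBR distance 1, by filtering the full
    enumeration with the definition-level check."""
    labels = sorted(tree.leaf_labels())
    out = set()
    for cand in enumerate_unrooted_topologies(labels):
        if is_tbr_neighbor(tree, cand):
            out.add(cand.topology_key())
    return out


def scp_numeric_oracle(tree: Tree, tips: dict[str, float]) -> tuple[float, dict]:
    """Minimise the squared-change objective with a generic optimizer."""
    from scipy.optimize import minimize

    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    values = {id(n): tips[n.label] for n in nodes if n.is_leaf}

    def objective(x):
        vals = dict(values)
        for n, v in zip(internal, x):
            vals[id(n)] = v
        return sum(
            (vals[id(n)] - vals[id(n.parent)]) ** 2
            for n in nodes
            if n.parent is not None
        )

    x0 = np.full(len(internal), np.mean(list(tips.values())))
    res = minimize(objective, x0, method="L-BFGS-B", tol=1e-14)
    vals = {id(n): tips[n.label] for n in nodes if n.is_leaf}
    for n, v in zip(internal, res.x):
        vals[id(n)] = float(v)
    return float(res.fun), vals


def scp_iterative_oracle(tree: Tree, tips: dict[str, float], sweeps: int = 20000) -> float:
    """Local averaging to convergence: repeatedly set every internal
    value to the mean of its neighbours; returns the objective."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    value = {id(n): (tips[n.label] if n.is_leaf else float(np.mean(list(tips.values())))) for n in nodes}
    for _ in range(sweeps):
        delta = 0.0
        for n in internal:
            nbrs = list(n.children) + ([n.parent] if n.parent else [])
            new = sum(value[id(x)] for x in nbrs) / len(nbrs)
            delta = max(delta, abs(new - value[id(n)]))
            value[id(n)] = new
        if delta < 1e-13:
            break
    return sum(
        (value[id(n)] - value[id(n.parent)]) ** 2
        for n in nodes
        if n.parent is not None
    )
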