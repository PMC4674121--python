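"""Heuristic maximum-parsimony tree search.

Search strategy: random-addition-sequence starting trees, each refined
by tree-bisection-reconnection (TBR) hill climbing, followed by a
plateau phase that also swaps on every tied tree so the full set of
most-parsimonious trees (MPTs) reachable by TBR is collected, up to a
retention cap.  Trees are unrooted and binary during search; the strict
consensus may contain polytomies.

Internally a tree is an adjacency map ``{node_id: [neighbour_ids]}``
with leaves numbered ``0..n-1`` (row order of the matrix).  Scoring
uses the packed big-integer Fitch engine from
:mod:`parsimorph.parsimony_core`; for each TBR bisection the two
fragments' Fitch state sets are computed once per fragment edge, so a
reconnection is scored in O(1) big-integer operations.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .matrix import CharacterMatrix, _norm_label
from .parsimony_core import PackedMatrix
from .tree import Node, Tree

Adj = dict[int, list[int]]


@dataclass
class SearchConfig:
    n_addition_replicates: int = 100
    seed: int = 0
    max_trees_retained: int = 10_000
    steepest_descent: bool = False

    def __post_init__(self) -> None:
        if self.n_addition_replicates < 1:
            raise ValueError("n_addition_replicates must be >= 1")


@dataclass
class SearchResult:
    best_length: int
    best_trees: list[Tree]
    log: list[dict] = field(default_factory=list)
    truncated: bool = False
    seed: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.best_trees)


# ---------------------------------------------------------------------------
# adjacency-map primitives
# ---------------------------------------------------------------------------


def _preorder_edges(adj: Adj, root: int) -> list[tuple[int | None, int]]:
    order: list[tuple[int | None, int]] = []
    stack: list[tuple[int | None, int]] = [(None, root)]
    while stack:
        parent, node = stack.pop()
        order.append((parent, node))
        for nb in adj[node]:
            if nb != parent:
                stack.append((node, nb))
    return order


def _edges(adj: Adj) -> list[tuple[int, int]]:
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _is_leaf(adj: Adj, x: int) -> bool:
    return len(adj[x]) == 1


def _dir_sets(adj: Adj, packed: PackedMatrix) -> dict[tuple[int, int], tuple[int, int]]:
    """Fitch (state-set vector, cost) of the component containing ``b``
    when edge {a, b} is removed, keyed by directed edge (a, b)."""
    rows = packed.rows
    root = min(x for x in adj if _is_leaf(adj, x))
    pre = _preorder_edges(adj, root)
    D: dict[tuple[int, int], tuple[int, int]] = {}
    for parent, node in reversed(pre):
        if parent is None:
            continue
        if _is_leaf(adj, node):
            D[(parent, node)] = (rows[node], 0)
        else:
            kids = [nb for nb in adj[node] if nb != parent]
            s, c = D[(node, kids[0])]
            for k in kids[1:]:
                s2, c2 = D[(node, k)]
                s, extra = packed.combine(s, s2)
                c += c2 + extra
            D[(parent, node)] = (s, c)
    for parent, node in pre:
        if parent is None:
            continue
        if _is_leaf(adj, parent):
            D[(node, parent)] = (rows[parent], 0)
        else:
            others = [nb for nb in adj[parent] if nb != node]
            s, c = D[(parent, others[0])]
            for o in others[1:]:
                s2, c2 = D[(parent, o)]
                s, extra = packed.combine(s, s2)
                c += c2 + extra
            D[(node, parent)] = (s, c)
    return D


def _score(adj: Adj, packed: PackedMatrix) -> int:
    """Total Fitch length of the unrooted tree."""
    rows = packed.rows
    root = min(x for x in adj if _is_leaf(adj, x))
    pre = _preorder_edges(adj, root)
    D: dict[int, tuple[int, int]] = {}
    for parent, node in reversed(pre):
        if parent is None:
            continue
        if _is_leaf(adj, node):
            D[node] = (rows[node], 0)
        else:
            kids = [nb for nb in adj[node] if nb != parent]
            s, c = D[kids[0]]
            for k in kids[1:]:
                s2, c2 = D[k]
                s, extra = packed.combine(s, s2)
                c += c2 + extra
            D[node] = (s, c)
    nb = adj[root][0]
    s, c = D[nb]
    return c + packed.join_cost(rows[root], s)


def _splits_key(adj: Adj, n_leaves: int) -> frozenset[int]:
    """Unrooted topology identity: nontrivial splits as leaf bitmasks
    (side not containing leaf 0)."""
    full = (1 << n_leaves) - 1
    root = 0
    pre = _preorder_edges(adj, root)
    mask: dict[int, int] = {}
    key: set[int] = set()
    for parent, node in reversed(pre):
        if node < n_leaves:
            mask[node] = 1 << node
        else:
            m = 0
            for nb in adj[node]:
                if nb != parent:
                    m |= mask[nb]
            mask[node] = m
        if parent is not None:
            m = mask[node]
            side = m if not (m & 1) else full ^ m
            c = side.bit_count()
            if 2 <= c <= n_leaves - 2:
                key.add(side)
    return frozenset(key)


# ---------------------------------------------------------------------------
# conversions between Tree objects and adjacency maps
# ---------------------------------------------------------------------------


def _tree_to_adj(tree: Tree, taxa: Sequence[str]) -> Adj:
    index = {_norm_label(t): i for i, t in enumerate(taxa)}
    n = len(taxa)
    adj: Adj = {}
    next_id = n

    def add_edge(a: int, b: int) -> None:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def visit(node: Node) -> int:
        nonlocal next_id
        if node.is_leaf:
            return index[_norm_label(node.label or "")]
        me = next_id
        next_id += 1
        adj.setdefault(me, [])
        for child in node.children:
            add_edge(me, visit(child))
        return me

    root = tree.root
    if not root.is_leaf and len(root.children) == 2:
        a = visit(root.children[0])
        b = visit(root.children[1])
        add_edge(a, b)
    else:
        visit(root)
    return adj


def _adj_to_tree(adj: Adj, taxa: Sequence[str]) -> Tree:
    """Materialise as a Tree rooted on the edge incident to leaf 0."""
    n = len(taxa)

    def build(node: int, parent: int) -> Node:
        if node < n:
            return Node(label=taxa[node])
        out = Node()
        for nb in adj[node]:
            if nb != parent:
                out.add(build(nb, node))
        return out

    root = Node()
    nb = adj[0][0]
    root.add(Node(label=taxa[0]))
    root.add(build(nb, 0))
    return Tree(root)


# ---------------------------------------------------------------------------
# random-addition starting trees
# ---------------------------------------------------------------------------


def _random_addition(packed: PackedMatrix, rng: random.Random) -> Adj:
    n = len(packed.rows)
    rows = packed.rows
    order = list(range(n))
    rng.shuffle(order)
    a, b, c = order[:3]
    hub = n
    adj: Adj = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    next_id = n + 1
    for leaf in order[3:]:
        D = _dir_sets(adj, packed)
        best_cost: int | None = None
        best_edges: list[tuple[int, int]] = []
        for u, v in _edges(adj):
            su, cu = D[(v, u)]
            sv, cv = D[(u, v)]
            s, extra = packed.combine(su, sv)
            cost = cu + cv + extra + packed.join_cost(s, rows[leaf])
            if best_cost is None or cost < best_cost:
                best_cost, best_edges = cost, [(u, v)]
            elif cost == best_cost:
                best_edges.append((u, v))
        u, v = best_edges[rng.randrange(len(best_edges))]
        w = next_id
        next_id += 1
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].append(w)
        adj[v].append(w)
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
    return adj


def random_addition_tree(matrix: CharacterMatrix, rng: random.Random | int) -> Tree:
    """Stepwise-addition starting tree: taxa inserted in random order,
    each at the attachment point of minimum incremental Fitch length."""
    if isinstance(rng, int):
        rng = random.Random(rng)
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    packed = PackedMatrix.from_character_matrix(matrix)
    return _adj_to_tree(_random_addition(packed, rng), matrix.taxa)


# ---------------------------------------------------------------------------
# TBR moves
# ---------------------------------------------------------------------------

# A reattachment position is ('leaf', leaf_id) for a single-leaf fragment
# or ('edge', (p, q)) for a fragment edge to be subdivided.
Position = tuple[str, object]


def _fragment_nodes(adj: Adj, start: int, banned: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for nb in adj[x]:
            if nb != banned and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _fragment_adj(adj: Adj, nodes: set[int], cut_end: int) -> tuple[Adj, Position]:
    """Restrict ``adj`` to ``nodes``, suppressing the degree-2 node left
    at ``cut_end``; returns the fragment and the original attachment
    position within it."""
    sub: Adj = {x: [nb for nb in adj[x] if nb in nodes] for x in nodes}
    if len(sub[cut_end]) == 2:
        p, q = sub[cut_end]
        sub[p] = [q if y == cut_end else y for y in sub[p]]
        sub[q] = [p if y == cut_end else y for y in sub[q]]
        del sub[cut_end]
        return sub, ("edge", (min(p, q), max(p, q)))
    return sub, ("leaf", cut_end)


def _root_infos(
    frag: Adj, packed: PackedMatrix
) -> list[tuple[Position, int, int]]:
    """(position, state-set vector, cost) for every way of rooting the
    fragment: at its single leaf, or on any of its edges."""
    if len(frag) == 1:
        leaf = next(iter(frag))
        return [(("leaf", leaf), packed.rows[leaf], 0)]
    D = _dir_sets(frag, packed)
    out: list[tuple[Position, int, int]] = []
    for u, v in _edges(frag):
        su, cu = D[(v, u)]
        sv, cv = D[(u, v)]
        s, extra = packed.combine(su, sv)
        out.append((("edge", (u, v)), s, cu + cv + extra))
    return out


def _tbr_moves(
    adj: Adj, packed: PackedMatrix
) -> Iterator[tuple[int, tuple[int, int], Position, Position]]:
    """Yield (length, bisected_edge, position_in_A, position_in_B) for
    every TBR reconnection; the identity reconnection is skipped."""
    for u, v in _edges(adj):
        nodes_a = _fragment_nodes(adj, u, v)
        if len(nodes_a) == 1 and len(adj) - len(nodes_a) == 1:
            continue  # 2-taxon tree, nothing to do
        nodes_b = set(adj) - nodes_a
        frag_a, orig_a = _fragment_adj(adj, nodes_a, u)
        frag_b, orig_b = _fragment_adj(adj, nodes_b, v)
        infos_a = _root_infos(frag_a, packed)
        infos_b = _root_infos(frag_b, packed)
        for pos_a, sa, ca in infos_a:
            for pos_b, sb, cb in infos_b:
                if pos_a == orig_a and pos_b == orig_b:
                    continue
                yield (
                    ca + cb + packed.join_cost(sa, sb),
                    (u, v),
                    pos_a,
                    pos_b,
                )


def _apply_move(
    adj: Adj, edge: tuple[int, int], pos_a: Position, pos_b: Position
) -> Adj:
    new: Adj = {x: list(nbs) for x, nbs in adj.items()}
    u, v = edge
    new[u].remove(v)
    new[v].remove(u)
    freed: list[int] = []
    for x in (u, v):
        if len(new[x]) == 2:
            p, q = new[x]
            new[p] = [q if y == x else y for y in new[p]]
            new[q] = [p if y == x else y for y in new[q]]
            del new[x]
            freed.append(x)

    def attach(pos: Position) -> int:
        if pos[0] == "leaf":
            return pos[1]  # type: ignore[return-value]
        p, q = pos[1]  # type: ignore[misc]
        w = freed.pop()
        new[p] = [w if y == q else y for y in new[p]]
        new[q] = [w if y == p else y for y in new[q]]
        new[w] = [p, q]
        return w

    xa = attach(pos_a)
    xb = attach(pos_b)
    new[xa].append(xb)
    new[xb].append(xa)
    return new


def tbr_neighbors(tree: Tree) -> Iterator[Tree]:
    """All distinct unrooted topologies one TBR rearrangement away.

    Requires a binary tree with at least 4 leaves; neither the input
    topology nor any duplicate is yielded.
    """
    taxa = sorted(tree.leaf_labels())
    if len(taxa) < 4:
        raise ValueError("TBR needs at least 4 leaves")
    n = len(taxa)
    adj = _tree_to_adj(tree, taxa)
    for x, nbs in adj.items():
        if x >= n and len(nbs) != 3:
            raise ValueError("TBR requires a fully binary (unrooted) tree")
    # scoring is irrelevant here; use a trivial packed matrix
    packed = PackedMatrix(taxa, [[1] for _ in taxa], 1)
    seen = {_splits_key(adj, n)}
    for _, edge, pos_a, pos_b in _tbr_moves(adj, packed):
        new = _apply_move(adj, edge, pos_a, pos_b)
        key = _splits_key(new, n)
        if key not in seen:
            seen.add(key)
            yield _adj_to_tree(new, taxa)


# ---------------------------------------------------------------------------
# hill climbing and plateau collection
# ---------------------------------------------------------------------------


def _hill_climb(
    adj: Adj, packed: PackedMatrix, steepest: bool = False
) -> tuple[Adj, int, int]:
    cur = _score(adj, packed)
    tried = 0
    while True:
        best: tuple[int, tuple[int, int], Position, Position] | None = None
        for move in _tbr_moves(adj, packed):
            tried += 1
            if move[0] < cur:
                if not steepest:
                    best = move
                    break
                if best is None or move[0] < best[0]:
                    best = move
        if best is None:
            return adj, cur, tried
        adj = _apply_move(adj, best[1], best[2], best[3])
        cur = best[0]


def _collect_plateau(
    starts: list[Adj], packed: PackedMatrix, max_trees: int
) -> tuple[int, dict[frozenset[int], Adj], bool]:
    """TBR closure over all trees tying the best length; restarts if a
    shorter tree is discovered while swapping on ties."""
    n = len(packed.rows)
    best = min(_score(a, packed) for a in starts)
    pool: dict[frozenset[int], Adj] = {}
    for a in starts:
        if _score(a, packed) == best:
            pool.setdefault(_splits_key(a, n), a)
    truncated = False
    while True:
        queue = deque(pool.values())
        visited = set(pool)
        improved: Adj | None = None
        while queue:
            adj = queue.popleft()
            for cost, edge, pa, pb in _tbr_moves(adj, packed):
                if cost < best:
                    improved = _apply_move(adj, edge, pa, pb)
                    best = cost
                    break
                if cost == best:
                    new = _apply_move(adj, edge, pa, pb)
                    key = _splits_key(new, n)
                    if key not in visited:
                        if len(pool) >= max_trees:
                            truncated = True
                        else:
                            visited.add(key)
                            pool[key] = new
                            queue.append(new)
            if improved is not None:
                break
        if improved is None:
            return best, pool, truncated
        improved, best, _ = _hill_climb(improved, packed)
        best = _score(improved, packed)
        pool = {_splits_key(improved, n): improved}
        truncated = False


def heuristic_search(
    matrix: CharacterMatrix, config: SearchConfig | None = None
) -> SearchResult:
    """Random-addition + TBR search for minimum-length trees.

    Retains every distinct unrooted topology tying the best length
    found (plateau closure by swapping on tied trees), up to
    ``config.max_trees_retained``.
    """
    config = config or SearchConfig()
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    packed = PackedMatrix.from_character_matrix(matrix)
    rng = random.Random(config.seed)
    log: list[dict] = [{"seed": config.seed, "replicates": config.n_addition_replicates}]
    best_len: int | None = None
    optima: list[Adj] = []
    for rep in range(config.n_addition_replicates):
        adj = _random_addition(packed, rng)
        start_len = _score(adj, packed)
        adj, end_len, tried = _hill_climb(adj, packed, config.steepest_descent)
        log.append(
            {
                "replicate": rep,
                "start_length": start_len,
                "end_length": end_len,
                "rearrangements_tried": tried,
            }
        )
        if best_len is None or end_len < best_len:
            best_len = end_len
            optima = [adj]
        elif end_len == best_len:
            optima.append(adj)
    assert best_len is not None
    best_len, pool, truncated = _collect_plateau(
        optima, packed, config.max_trees_retained
    )
    if truncated:
        log.append({"warning": "max_trees_retained exceeded; MPT set truncated"})
    trees = [_adj_to_tree(a, matrix.taxa) for a in pool.values()]
    return SearchResult(
        best_length=best_len,
        best_trees=trees,
        log=log,
        truncated=truncated,
        seed=config.seed,
    )


def collect_trees_within(
    matrix: CharacterMatrix,
    starts: list[Tree],
    slack: int,
    max_trees: int = 20_000,
) -> tuple[list[Tree], bool]:
    """TBR closure over all trees within ``slack`` steps of the best
    length among ``starts`` (used for Bremer decay).  Returns the
    collected trees and a truncation flag."""
    packed = PackedMatrix.from_character_matrix(matrix)
    n = matrix.n_taxa
    adjs = [_tree_to_adj(t, matrix.taxa) for t in starts]
    limit = min(_score(a, packed) for a in adjs) + slack
    pool: dict[frozenset[int], Adj] = {}
    for a in adjs:
        pool.setdefault(_splits_key(a, n), a)
    queue = deque(pool.values())
    truncated = False
    while queue:
        adj = queue.popleft()
        for cost, edge, pa, pb in _tbr_moves(adj, packed):
            if cost <= limit:
                new = _apply_move(adj, edge, pa, pb)
                key = _splits_key(new, n)
                if key not in pool:
                    if len(pool) >= max_trees:
                        truncated = True
                        continue
                    pool[key] = new
                    queue.append(new)
    return [_adj_to_tree(a, matrix.taxa) for a in pool.values()], truncated


# ---------------------------------------------------------------------------
# consensus, collapse, exhaustive enumeration
# ---------------------------------------------------------------------------


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree whose clades are exactly the bipartitions shared by all
    inputs; conflicts become polytomies."""
    if not trees:
        raise ValueError("no trees given")
    leaf_sets = {t.leaf_set() for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("trees have differing leaf sets")
    (leaves,) = leaf_sets
    shared = frozenset.intersection(*(t.bipartitions() for t in trees))
    return tree_from_splits(shared, leaves)


def majority_rule_consensus(
    split_counts: dict[frozenset[str], int], n_inputs: int, leaves: frozenset[str]
) -> Tree:
    """Majority-rule tree from split tallies (splits in > half the inputs)."""
    majority = frozenset(
        s for s, c in split_counts.items() if c * 2 > n_inputs
    )
    return tree_from_splits(majority, leaves)


def tree_from_splits(
    splits: frozenset[frozenset[str]], leaves: frozenset[str]
) -> Tree:
    """Build the (rooted-for-display) tree realising a compatible split set."""
    ref = min(leaves) if leaves else ""
    sides = {s if ref not in s else leaves - s for s in splits}
    sides = {s for s in sides if 2 <= len(s) <= len(leaves) - 2}

    def build(members: frozenset[str], inner: list[frozenset[str]]) -> Node:
        node = Node()
        maximal = [s for s in inner if not any(s < t for t in inner)]
        covered: set[str] = set().union(*maximal) if maximal else set()
        for leaf in sorted(members - covered):
            node.add(Node(label=leaf))
        for s in sorted(maximal, key=lambda s: min(s)):
            node.add(build(s, [t for t in inner if t < s]))
        return node

    inner = [s for s in sides if s < leaves]
    return Tree(build(frozenset(leaves), inner))


def collapse_ambiguous_edges(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Collapse internal branches whose minimum length is zero (i.e.
    every character admits an optimal labeling with no change there)."""
    packed = PackedMatrix.from_character_matrix(matrix)
    n = matrix.n_taxa
    adj = _tree_to_adj(tree, matrix.taxa)
    D = _dir_sets(adj, packed)
    parent_of: dict[int, int] = {}
    group = {x: x for x in adj}

    def find(x: int) -> int:
        while group[x] != x:
            group[x] = group[group[x]]
            x = group[x]
        return x

    for u, v in _edges(adj):
        if u >= n and v >= n:
            su, _ = D[(v, u)]
            sv, _ = D[(u, v)]
            if packed.join_cost(su, sv) == 0:
                group[find(u)] = find(v)
    merged: Adj = {}
    for u, v in _edges(adj):
        gu, gv = find(u), find(v)
        if gu != gv:
            merged.setdefault(gu, []).append(gv)
            merged.setdefault(gv, []).append(gu)
    for leaf in range(n):
        merged.setdefault(find(leaf), [])

    def build(node: int, parent: int | None) -> Node:
        if node < n:
            return Node(label=matrix.taxa[node])
        out = Node()
        for nb in merged[node]:
            if nb != parent:
                out.add(build(nb, node))
        return out

    leaf0_hub = merged[find(0)][0] if merged[find(0)] else find(0)
    root = Node()
    root.add(Node(label=matrix.taxa[0]))
    root.add(build(leaf0_hub, find(0)))
    return Tree(root)


def enumerate_unrooted_topologies(labels: Sequence[str]) -> Iterator[Tree]:
    """Every unrooted binary topology on the labels (1, 3, 15, 105, 945,
    ... trees for 3, 4, 5, 6, 7 leaves)."""
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 labels")

    def grow(adj: Adj, next_leaf: int, next_internal: int) -> Iterator[Adj]:
        if next_leaf == n:
            yield adj
            return
        for u, v in _edges(adj):
            new: Adj = {x: list(nbs) for x, nbs in adj.items()}
            w = next_internal
            new[u].remove(v)
            new[v].remove(u)
            new[u].append(w)
            new[v].append(w)
            new[w] = [u, v, next_leaf]
            new[next_leaf] = [w]
            yield from grow(new, next_leaf + 1, next_internal + 1)

    hub = n
    base: Adj = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}
    for adj in grow(base, 3, n + 1):
        yield _adj_to_tree(adj, labels)


def exhaustive_search(matrix: CharacterMatrix) -> tuple[int, list[Tree]]:
    """Exact search by enumerating all unrooted topologies (small n only)."""
    packed = PackedMatrix.from_character_matrix(matrix)
    best: int | None = None
    winners: list[Tree] = []
    for tree in enumerate_unrooted_topologies(matrix.taxa):
        adj = _tree_to_adj(tree, matrix.taxa)
        score = _score(adj, packed)
        if best is None or score < best:
            best, winners = score, [tree]
        elif score == best:
            winners.append(tree)
    assert best is not None
    return best, winners


def root_on_outgroup(tree: Tree, outgroup: Sequence[str], strict: bool = False) -> Tree:
    """Reroot (for display) on the branch separating ``outgroup`` from
    the rest; returns the tree unchanged if that split is absent and
    ``strict`` is false."""
    want = frozenset(_norm_label(o) for o in outgroup)
    leaves = tree.leaf_set()
    work = tree.copy()
    for node in work.postorder():
        below = frozenset(
            _norm_label(l.label or "") for l in Tree(node).leaves()
        )
        if below in (want, leaves - want) and node.parent is not None:
            parent = node.parent
            parent.children.remove(node)
            node.parent = None
            # reorient the remainder of the tree below the new root
            path = []
            p: Node | None = parent
            while p is not None:
                path.append(p)
                p = p.parent
            for child, par in zip(path, path[1:]):
                par.children.remove(child)
                child.add(par)
            new_root = Node()
            new_root.add(node)
            new_root.add(parent)
            out = Tree(new_root)
            out.suppress_unifurcations()
            return out
    if strict:
        raise ValueError("outgroup does not correspond to a split in the tree")
    return tree
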