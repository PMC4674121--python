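"""Clade support: nonparametric bootstrap and Bremer decay indices.

Bootstrap: each replicate resamples characters with replacement, runs a
reduced-effort heuristic search, and contributes the splits of that
replicate's strict consensus of best trees (one vote per replicate per
split).  Bremer decay: the smallest extra length k at which a clade
drops out of the strict consensus of all trees within k steps of the
optimum; collection of near-optimal trees is heuristic (TBR closure),
so decay values are exact only where the closure is (small taxon
counts are cross-checked against exhaustive enumeration in the tests).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .matrix import CharacterMatrix
from .tree import Tree
from .tree_search import (
    SearchConfig,
    SearchResult,
    collect_trees_within,
    heuristic_search,
    majority_rule_consensus,
    strict_consensus,
)


@dataclass
class SupportSummary:
    clades: list[frozenset[str]]
    bootstrap_pct: dict[frozenset[str], float] = field(default_factory=dict)
    decay_index: dict[frozenset[str], float] = field(default_factory=dict)
    majority_tree: Tree | None = None
    consensus_tree: Tree | None = None
    replicate_splits: list[frozenset[frozenset[str]]] = field(default_factory=list)
    n_replicates: int = 0
    k_max: int | None = None
    truncated: bool = False


def split_key(clade, leaves) -> frozenset[str]:
    """Canonical key for an unrooted split: the side not containing the
    lexicographically smallest leaf."""
    clade = frozenset(clade)
    leaves = frozenset(leaves)
    return clade if min(leaves) not in clade else leaves - clade


def _resample_matrix(
    matrix: CharacterMatrix, rng: random.Random
) -> CharacterMatrix:
    indices = [rng.randrange(matrix.n_chars) for _ in range(matrix.n_chars)]
    rows = [[row[i] for i in indices] for row in matrix.rows]
    return CharacterMatrix(matrix.taxa, rows)


def bootstrap_support(
    matrix: CharacterMatrix,
    n_replicates: int = 100,
    seed: int = 0,
    search_config: SearchConfig | None = None,
) -> SupportSummary:
    """Character-resampling bootstrap percentages per split."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = search_config or SearchConfig(n_addition_replicates=10)
    rng = random.Random(seed)
    counts: dict[frozenset[str], int] = {}
    replicate_splits: list[frozenset[frozenset[str]]] = []
    for _ in range(n_replicates):
        resampled = _resample_matrix(matrix, rng)
        config = SearchConfig(
            n_addition_replicates=base.n_addition_replicates,
            seed=rng.randrange(2**31),
            max_trees_retained=min(base.max_trees_retained, 500),
            steepest_descent=base.steepest_descent,
        )
        result = heuristic_search(resampled, config)
        consensus = strict_consensus(result.best_trees)
        splits = consensus.bipartitions()
        replicate_splits.append(splits)
        for s in splits:
            counts[s] = counts.get(s, 0) + 1
    pct = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    leaves = frozenset(t.replace("_", " ").strip() for t in matrix.taxa)
    majority = majority_rule_consensus(counts, n_replicates, leaves)
    return SupportSummary(
        clades=sorted(pct, key=lambda s: (-pct[s], sorted(s))),
        bootstrap_pct=pct,
        majority_tree=majority,
        replicate_splits=replicate_splits,
        n_replicates=n_replicates,
    )


def bremer_decay(
    matrix: CharacterMatrix,
    k_max: int = 3,
    search_config: SearchConfig | None = None,
    search_result: SearchResult | None = None,
    max_trees: int = 20_000,
) -> SupportSummary:
    """Decay index per split of the MPT strict consensus.

    Splits surviving at ``k_max`` are reported as ``math.inf``
    (meaning "> k_max"); splits absent from some MPT get 0.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    result = search_result or heuristic_search(
        matrix, search_config or SearchConfig()
    )
    consensus = strict_consensus(result.best_trees)
    target_splits = consensus.bipartitions()
    all_mpt_splits = frozenset().union(
        *(t.bipartitions() for t in result.best_trees)
    )
    decay: dict[frozenset[str], float] = {
        s: 0.0 for s in all_mpt_splits - target_splits
    }
    remaining = set(target_splits)
    truncated = False
    for k in range(1, k_max + 1):
        if not remaining:
            break
        pool, trunc = collect_trees_within(
            matrix, result.best_trees, slack=k, max_trees=max_trees
        )
        truncated = truncated or trunc
        surviving = frozenset.intersection(*(t.bipartitions() for t in pool))
        for s in list(remaining):
            if s not in surviving:
                decay[s] = float(k)
                remaining.discard(s)
    for s in remaining:
        decay[s] = math.inf
    return SupportSummary(
        clades=sorted(target_splits, key=lambda s: sorted(s)),
        decay_index=decay,
        consensus_tree=consensus,
        k_max=k_max,
        truncated=truncated,
    )


def annotate_tree_with_support(tree: Tree, summary: SupportSummary) -> Tree:
    """Copy of ``tree`` with bootstrap percentages as internal labels."""
    out = tree.copy()
    leaves = out.leaf_set()
    ref = min(leaves)
    for node in out.postorder():
        if node.is_leaf or node.parent is None:
            continue
        below = frozenset(l.replace("_", " ") for l in Tree(node).leaf_labels())
        side = below if ref not in below else leaves - below
        if side in summary.bootstrap_pct:
            node.label = f"{summary.bootstrap_pct[side]:.0f}"
    return out


def support_table(summary: SupportSummary):
    """TSV-ready table: clade members, bootstrap %, decay index."""
    import pandas as pd

    clades = sorted(
        set(summary.bootstrap_pct) | set(summary.decay_index),
        key=lambda s: (len(s), sorted(s)),
    )
    rows = []
    for clade in clades:
        decay = summary.decay_index.get(clade)
        if decay is not None and math.isinf(decay):
            decay = f"> {summary.k_max}" if summary.k_max else "> k_max"
        rows.append(
            {
                "clade": "|".join(sorted(clade)),
                "bootstrap_pct": summary.bootstrap_pct.get(clade),
                "decay": decay,
            }
        )
    return pd.DataFrame(rows)
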