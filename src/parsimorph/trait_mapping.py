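"""Squared-change parsimony mapping of a continuous trait onto a tree.

Tip values (condylobasal length in cm, a cetacean body-size proxy) are
fixed; internal-node values are chosen to minimise the sum over edges
of squared parent-child differences.  Edges are unweighted (the
consensus tree carries no branch lengths), which makes the optimum the
solution of a positive-definite linear system: at the minimum every
internal node equals the mean of its neighbours.  Reconstructed values
can be discretised into equal-width bins for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from .matrix import TraitTable, _norm_label
from .tree import Node, Tree


@dataclass
class TraitReconstruction:
    tree: Tree  # copy with node.value (and node.bin) filled in
    objective: float
    node_values: dict[int, float] = field(default_factory=dict)  # id(node) -> value
    n_bins: int | None = None
    bins: dict[int, int] = field(default_factory=dict)  # id(node) -> bin 1..n_bins


def squared_change_parsimony(
    tree: Tree, traits: TraitTable | dict[str, float]
) -> TraitReconstruction:
    """Globally minimise Σ_edges (v_parent − v_child)² with tips fixed.

    ``traits`` may be a :class:`TraitTable` or any label → value
    mapping.  Solved directly via the (sparse) normal equations; the
    root value is reported like any internal value but depends on root
    placement only through the tree's edge set.
    """
    if isinstance(traits, TraitTable):
        lookup = {k: v for k, v in traits.values.items()}
    else:
        lookup = {_norm_label(k): float(v) for k, v in traits.items()}
    work = tree.copy()
    nodes = list(work.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    index = {id(n): i for i, n in enumerate(internal)}

    for leaf in work.leaves():
        label = _norm_label(leaf.label or "")
        if label not in lookup:
            raise ValueError(f"tip {leaf.label!r} has no trait value")
        leaf.value = lookup[label]

    m = len(internal)
    if m == 0:
        raise ValueError("tree has no internal nodes")
    A = lil_matrix((m, m))
    b = np.zeros(m)
    for node in internal:
        i = index[id(node)]
        neighbours = list(node.children)
        if node.parent is not None:
            neighbours.append(node.parent)
        A[i, i] = len(neighbours)
        for nb in neighbours:
            if nb.is_leaf:
                b[i] += nb.value
            else:
                A[i, index[id(nb)]] -= 1
    solution = spsolve(A.tocsr(), b)
    if m == 1:
        solution = np.atleast_1d(solution)
    for node, value in zip(internal, solution):
        node.value = float(value)

    objective = 0.0
    for node in nodes:
        if node.parent is not None:
            objective += (node.value - node.parent.value) ** 2
    return TraitReconstruction(
        tree=work,
        objective=float(objective),
        node_values={id(n): float(n.value) for n in work.postorder()},
    )


def bin_traits(recon: TraitReconstruction, n_bins: int = 6) -> TraitReconstruction:
    """Assign every node an equal-width bin 1..n_bins over the value range.

    The last bin is right-closed; a degenerate range puts everything in
    bin 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = [n.value for n in recon.tree.postorder()]
    lo, hi = min(values), max(values)
    if hi == lo:
        assignment = {id(n): 1 for n in recon.tree.postorder()}
    else:
        width = (hi - lo) / n_bins
        assignment = {
            id(n): min(n_bins, int((n.value - lo) / width) + 1)
            for n in recon.tree.postorder()
        }
    for node in recon.tree.postorder():
        node.bin = assignment[id(node)]
    recon.n_bins = n_bins
    recon.bins = assignment
    return recon


def annotate_tree_with_strat_ranges(
    tree: Tree, ranges: dict[str, tuple[float, float]]
) -> Tree:
    """Attach (first, last) stratigraphic occurrence ages (Ma) to tips.

    Ages decrease toward the present, so ``first >= last > =0`` is
    required.  No computation happens beyond validation; an empty range
    set returns the tree unchanged.
    """
    if not ranges:
        return tree
    by_label = {_norm_label(l.label or ""): l for l in tree.leaves()}
    for taxon, (first, last) in ranges.items():
        key = _norm_label(taxon)
        if key not in by_label:
            raise ValueError(f"taxon {taxon!r} not a tip of the tree")
        if first < last:
            raise ValueError(
                f"inverted stratigraphic range for {taxon!r}: "
                f"first={first} Ma < last={last} Ma"
            )
        if first < 0 or last < 0:
            raise ValueError(f"negative age in range for {taxon!r}")
        by_label[key].meta["strat_range"] = (float(first), float(last))
    return tree


def reconstruction_table(recon: TraitReconstruction):
    """Per-node table: id, label, reconstructed value, bin."""
    import pandas as pd

    rows = []
    for i, node in enumerate(recon.tree.postorder()):
        rows.append(
            {
                "node": i,
                "label": node.label or "",
                "value": node.value,
                "bin": node.bin,
            }
        )
    return pd.DataFrame(rows)


def reconstruction_newick(recon: TraitReconstruction) -> str:
    """Newick with per-node value (and bin) annotations in comments."""

    def note(node: Node) -> str:
        parts = [f"value={node.value:.6g}"]
        if node.bin is not None:
            parts.append(f"bin={node.bin}")
        return ",".join(parts)

    return recon.tree.to_newick(include_lengths=False, annotate=note)
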