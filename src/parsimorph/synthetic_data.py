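"""Generators for inputs with the statistical structure the pipeline assumes.

The published character matrix and reference-measurement tables for the
physeteroid study exist only as supplementary images/documents, so this
module provides synthetic stand-ins with known ground truth:

* discrete character matrices evolved on a known tree under a
  symmetric Mk model (equal rates between all states), with missing
  and polymorphic cells injected at configurable rates;
* bivariate allometric reference tables with known slopes, intercepts
  and Gaussian residual noise.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix, StateSet, TraitTable
from .tree import Node, Tree


@dataclass(frozen=True)
class MkSimConfig:
    """Mk character-matrix simulation settings.

    ``rate`` is the expected number of substitutions per (unit-length)
    edge; the per-edge transition follows the k-state symmetric Markov
    chain, so P(change) = (k-1)/k · (1 − exp(−k·rate/(k−1))).
    """

    n_taxa: int = 21
    n_chars: int = 43
    n_states: int = 4
    rate: float = 0.1
    p_missing: float = 0.0
    p_polymorphic: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2 or self.n_states > 4:
            raise ValueError("n_states must be in 2..4 (states coded 0..3)")
        for p in (self.p_missing, self.p_polymorphic):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")


@dataclass(frozen=True)
class AllometrySimConfig:
    """Allometric reference-table simulation settings (cm units).

    Defaults mirror the published reference pipeline: 36 specimens and
    the printed coefficient pairs.  ``tl_mode`` picks which TL
    relationship is generative: "from_cbl" makes TL exactly linear in
    CBL (Method 1); "from_aon" makes TL − CBL exactly linear in AON
    (Method 2).  The other method's coefficients are then implied by
    the data rather than free parameters.
    """

    n_specimens: int = 36
    cbl_slope: float = 2.51
    cbl_intercept: float = 2.84
    m2_cbl_slope: float = 0.634
    m2_cbl_intercept: float = 31.2
    tl_slope: float = 3.4
    tl_intercept: float = 161.0
    m2_tl_slope: float = 6.33
    m2_tl_intercept: float = 31.2
    residual_sd: float = 5.0
    aon_range: tuple[float, float] = (10.0, 80.0)
    tl_mode: str = "from_cbl"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 3:
            raise ValueError("n_specimens must be >= 3")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.tl_mode not in ("from_cbl", "from_aon"):
            raise ValueError("tl_mode must be 'from_cbl' or 'from_aon'")


def simulate_tree(
    n_taxa: int, seed: int | random.Random, labels: list[str] | None = None
) -> Tree:
    """Random Yule (pure-birth) topology with unit edge lengths."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")
    root = Node()
    tips = [root.add(Node()), root.add(Node())]
    while len(tips) < n_taxa:
        tip = tips.pop(rng.randrange(len(tips)))
        tips.append(tip.add(Node()))
        tips.append(tip.add(Node()))
    for tip, label in zip(tips, labels):
        tip.label = label
    tree = Tree(root)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = 1.0
    return tree


def simulate_matrix(tree: Tree, config: MkSimConfig) -> CharacterMatrix:
    """Evolve unordered characters along ``tree`` under symmetric Mk.

    Missing cells ("?") and polymorphic cells (true state unioned with
    one random other state) are injected independently per cell.
    """
    rng = random.Random(config.seed)
    k = config.n_states
    length_scale = 1.0
    p_change = (
        0.0
        if config.rate == 0
        else (k - 1) / k * (1.0 - math.exp(-k * config.rate * length_scale / (k - 1)))
    )
    taxa = tree.leaf_labels()
    tip_states: dict[str, list[int]] = {t: [] for t in taxa}
    nodes = list(tree.preorder())
    for _ in range(config.n_chars):
        state: dict[int, int] = {id(tree.root): rng.randrange(k)}
        for node in nodes:
            if node.parent is None:
                continue
            s = state[id(node.parent)]
            if rng.random() < p_change:
                choices = [x for x in range(k) if x != s]
                s = choices[rng.randrange(k - 1)]
            state[id(node)] = s
            if node.is_leaf:
                tip_states[node.label or ""].append(s)

    full = frozenset(range(k))
    rows: list[list[StateSet]] = []
    for taxon in taxa:
        row: list[StateSet] = []
        for s in tip_states[taxon]:
            if rng.random() < config.p_missing:
                row.append(StateSet.missing(full))
            elif k > 1 and rng.random() < config.p_polymorphic:
                other = [x for x in range(k) if x != s]
                row.append(StateSet.of(s, other[rng.randrange(k - 1)]))
            else:
                row.append(StateSet.of(s))
        rows.append(row)
    return CharacterMatrix(taxa, rows)


def simulate_allometry(config: AllometrySimConfig) -> pd.DataFrame:
    """Reference-specimen table with columns specimen, AON, CBL, RL, TL."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.aon_range
    aon = rng.uniform(lo, hi, size=config.n_specimens)
    noise = lambda: rng.normal(0.0, config.residual_sd, size=config.n_specimens)
    cbl = config.cbl_slope * aon + config.cbl_intercept + noise()
    # RL is defined through the Method-2 relationship:
    # CBL − RL = m2_cbl_slope·AON + m2_cbl_intercept (+ noise)
    rl = cbl - (config.m2_cbl_slope * aon + config.m2_cbl_intercept + noise())
    if config.tl_mode == "from_cbl":
        tl = config.tl_slope * cbl + config.tl_intercept + noise()
    else:
        tl = cbl + config.m2_tl_slope * aon + config.m2_tl_intercept + noise()
    return pd.DataFrame(
        {
            "specimen": [f"ref{i + 1}" for i in range(config.n_specimens)],
            "AON": aon,
            "CBL": cbl,
            "RL": rl,
            "TL": tl,
        }
    )


# ---------------------------------------------------------------------------
# Synthetic stand-in for the physeteroid study inputs
# ---------------------------------------------------------------------------

#: The 21 operational taxonomic units of the physeteroid analysis.
STUDY_TAXA: tuple[str, ...] = (
    "Zygorhiza kochii",
    "Agorophius pygmaeus",
    "Physeter macrocephalus",
    "Kogia breviceps",
    "Kogia sima",
    "Aulophyseter morricei",
    "Orycterocetus crocodilinus",
    "Brygmophyseter shigensis",
    "Zygophyseter varolai",
    "Livyatan melvillei",
    "Acrophyseter deinodon",
    "Scaphokogia cochlearis",
    "Placoziphius duboisi",
    "Physeterula dubusi",
    "Thalassocetus antwerpiensis",
    "Praekogia cedrosensis",
    "Nanokogia isthmia",
    "Aprixokogia kelloggi",
    "Kogiopsis floridana",
    "Eudelphis mortezelensis",
    "Albicetus oxymycterus",
)

#: Synthetic condylobasal lengths (cm); plausible magnitudes only, not
#: measurements.  ``True`` marks values that would be proxy-taxon
#: substitutions in a real compilation.
_SYNTHETIC_CBL: dict[str, tuple[float, bool]] = {
    "Zygorhiza kochii": (92.0, False),
    "Agorophius pygmaeus": (60.0, True),
    "Physeter macrocephalus": (500.0, False),
    "Kogia breviceps": (42.0, False),
    "Kogia sima": (35.0, False),
    "Aulophyseter morricei": (120.0, False),
    "Orycterocetus crocodilinus": (110.0, False),
    "Brygmophyseter shigensis": (140.0, False),
    "Zygophyseter varolai": (150.0, False),
    "Livyatan melvillei": (300.0, False),
    "Acrophyseter deinodon": (100.0, False),
    "Scaphokogia cochlearis": (60.0, False),
    "Placoziphius duboisi": (80.0, False),
    "Physeterula dubusi": (100.0, False),
    "Thalassocetus antwerpiensis": (42.0, True),
    "Praekogia cedrosensis": (45.0, False),
    "Nanokogia isthmia": (45.0, True),
    "Aprixokogia kelloggi": (55.0, False),
    "Kogiopsis floridana": (70.0, False),
    "Eudelphis mortezelensis": (120.0, False),
    "Albicetus oxymycterus": (135.0, False),
}


def synthetic_study_matrix(seed: int = 7) -> CharacterMatrix:
    """SYNTHETIC stand-in for the study's 21 x 43 character matrix.

    Same shape and coding conventions as the real supplementary matrix
    (21 OTUs, 43 unordered characters, states 0-3, missing and
    polymorphic cells) but simulated under Mk on a random tree: its
    cell values, tree length and clade structure are NOT those of the
    published dataset.
    """
    rng = random.Random(seed)
    tree = simulate_tree(len(STUDY_TAXA), rng, labels=list(STUDY_TAXA))
    config = MkSimConfig(
        n_taxa=len(STUDY_TAXA),
        n_chars=43,
        n_states=4,
        rate=0.12,
        p_missing=0.2,
        p_polymorphic=0.02,
        seed=rng.randrange(2**31),
    )
    return simulate_matrix(tree, config)


def synthetic_study_traits() -> TraitTable:
    """SYNTHETIC condylobasal-length table for the 21 study taxa (cm)."""
    table = TraitTable()
    for taxon, (value, proxy) in _SYNTHETIC_CBL.items():
        table.add(taxon, value, proxy)
    return table
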