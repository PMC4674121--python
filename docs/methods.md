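# Methods

`parsimorph` implements the computational core of a fossil-sperm-whale
(Physeteroidea) systematics workflow: maximum-parsimony inference on a
morphological character matrix, clade-support statistics, squared-change
parsimony mapping of body size onto the tree, and a two-method
allometric pipeline estimating skull and body length from a rostral
width proxy. This note documents the models, the numerical choices, and
what the synthetic data generator does and does not emulate.

## Parsimony scoring

Characters are unordered multistate (states coded 0–9; in the target
dataset 0–3), so tree length is Fitch length: the minimum number of
state changes over all assignments of states to internal nodes.

* **General engine.** `fitch_length` runs a vectorised unit-cost
  Sankoff dynamic programme over all characters at once. Sankoff is
  exact on arbitrary trees, including polytomies (the strict consensus
  is generally multifurcating) and set-valued leaves.
* **Ambiguity semantics.** A polymorphic cell (`{01}`, `(01)` or
  `0/1`) and a missing cell (`?`, expanded to the full symbol set) are
  both treated as *uncertainty*: any one member state is acceptable at
  zero internal cost. This is the standard Fitch handling; true
  within-taxon polymorphism (every state must be reached) is not
  modelled. Missing data therefore contribute zero forced steps.
* **Fast path.** The heuristic search packs each taxon's candidate
  state sets into one large Python integer (one bit per state per
  character) and evaluates a binary Fitch combine in a handful of
  integer operations regardless of character count. The two engines are
  cross-checked against each other and against brute-force enumeration
  of internal labelings in the test suite.

Per-character bounds: the best case `min_steps` is (size of the
smallest state subset hitting every scoreable cell) − 1; the worst case
`max_steps` is (scoreable cells) − (largest achievable single-state
frequency), resolving polymorphic cells in favour of the dominant
state. These feed the ensemble consistency index CI = Σmin/L and
retention index RI = (Σmax − L)/(Σmax − Σmin). By convention CI = RI =
1 when L = 0, and the default includes parsimony-uninformative
characters in the sums (the common default of classic parsimony
software); `include_uninformative=False` drops characters whose best
and worst cases coincide.

## Heuristic search

`heuristic_search` performs random-addition-sequence starting trees
(taxa inserted in random order, each at the attachment of minimum
incremental length, ties broken by the seeded RNG) refined by
tree-bisection-reconnection (TBR). For each bisected edge the two
fragments' directional Fitch state sets are recomputed once per
fragment, after which every reconnection of fragment-edge pairs is
scored in O(1) big-integer operations. Descent is first-improvement by
default (`steepest_descent=True` switches to steepest).

**Plateau handling.** The set of most-parsimonious trees depends on
what a search does with equal-length rearrangements. The rule here:
after the replicates finish, swap on *every* tree tying the best
length and collect the TBR closure of that plateau, up to
`max_trees_retained` (default 10 000, truncation flagged and logged).
If the plateau phase stumbles on a shorter tree, the search restarts
from it. On all tested instances with ≤ 7 taxa this recovers exactly
the exhaustive-enumeration MPT set.

**Branch collapse.** Zero-minimum-length branches (internal edges on
which every character admits an optimal reconstruction with no change)
are *not* collapsed by default; `collapse_ambiguous_edges` implements
the alternative convention, and MPT counts can be reported under both.

**Rooting.** Search and scoring are unrooted; trees are rooted only
for display, by convention on the branch to the outgroups when that
split exists (`root_on_outgroup`).

A note on TBR neighbourhoods: at 5 leaves a cut fragment of one or two
leaves offers no re-rooting choice, so TBR coincides with SPR there and
a 5-leaf tree has 12 distinct TBR neighbours, not all 14 alternative
topologies. The test oracle is a definition-level fragment-restriction
check, independent of the move-generation code.

## Clade support

* **Bootstrap** (`bootstrap_support`): each replicate resamples
  characters with replacement, runs a reduced-effort search (default 10
  addition replicates + TBR; the full search's effort is unnecessary
  per replicate), and contributes the splits of that replicate's strict
  consensus — one vote per replicate per split, a convention that must
  be fixed because tallying all tied trees separately gives different
  numbers. A majority-rule summary tree is also built. All percentages
  are keyed by canonical unrooted splits (the side not containing the
  lexicographically smallest taxon; `split_key` normalises).
* **Bremer decay** (`bremer_decay`): for k = 1, 2, … the TBR closure of
  all trees within k steps of the optimum is collected
  (`collect_trees_within`, capped and truncation-flagged); a clade's
  decay index is the smallest k at which it drops out of the strict
  consensus of that pool. Clades surviving at `k_max` report ∞
  ("> k_max"); clades absent from some MPT report 0. The collection is
  heuristic, so exactness is guaranteed only at sizes where the
  exhaustive oracle runs (≤ 7 taxa in the tests).

## Squared-change parsimony

Condylobasal length (CBL, cm) is mapped onto the consensus tree by
minimising the sum over edges of squared parent–child differences with
tip values fixed. Edges are unweighted (the consensus carries no branch
lengths), the Maddison-style unweighted variant. The objective is a
positive-definite quadratic, solved directly via the sparse normal
equations; at the optimum every internal value is the mean of its
neighbours (verified to 1e-9), internal values lie within the tip
range, and the reconstruction is affine-equivariant. The root's value
is reported like any other internal value; with unweighted edges it
depends on the displayed root placement only through the edge set.
Reconstructed values are discretised into equal-width bins (default 6,
matching the display convention of the original figure; last bin
right-closed; degenerate range ⇒ all bin 1). Either CBL or total-length
values may be supplied; CBL is the default input. Stratigraphic ranges
(first/last occurrence, Ma, first ≥ last ≥ 0) can be attached to tips
as display metadata; no computation uses them.

## Allometric body-size pipeline

The type specimen preserves only a partial rostrum, so the single
usable proxy is the antorbital notch width (AON): the preserved right
half (24.7 cm) is doubled to a minimum full width of 49.4 cm. Two
bivariate OLS pipelines (statsmodels under the hood) give lower and
upper bounds:

* Method 1: CBL = 2.51·AON + 2.84, then TL = 3.4·CBL + 161;
* Method 2: (CBL − RL) = 0.634·AON + 31.2 with the preserved rostrum
  length RL = 81.9 cm added back, then TL = (6.33·AON + 31.2) + CBL.

Unrounded intermediates are carried end to end; rounding to 0.1 cm
happens only at report time (Method 1's TL consumes the *unrounded*
CBL: 3.4 × 126.834 + 161 = 592.2). With the published coefficients this
yields CBL 126.8–144.4 cm and Method-1 TL 592.2 cm. The published
Method-2 TL of 627.1 cm is **not** reproducible from the published
equation and inputs (6.33 × 49.4 + 31.2 + 144.4 = 488.3); the equation
is implemented exactly as printed, the coefficients are user-
configurable, and 627.1 is treated as an unverifiable constant rather
than encoded anywhere. `pipeline_from_data` refits all four
regressions from a reference table (columns AON, CBL, RL, TL; TL
present only for extant taxa) and requires ≥ 3 usable rows per
regression.

## Synthetic data

The study's character matrix and reference-measurement tables were
published only as supplementary images/documents, so every stage is
exercised on generated inputs with known ground truth:

* **Trees**: Yule (pure-birth) topologies, unit edge lengths.
* **Characters**: symmetric Mk with k ≤ 4 states; the per-edge
  transition uses the exact k-state Jukes–Cantor-type probability for
  the configured rate (expected substitutions per unit edge), so rate 0
  gives constant characters and large rates give uniform state
  frequencies. Missing cells and polymorphic cells (true state unioned
  with one random other state) are injected independently per cell.
  Equal rates, no rate heterogeneity across characters or branches, and
  no character correlation — real morphological matrices violate all
  three, so passing recovery tests demonstrate algorithmic correctness,
  not that real data meet Mk assumptions.
* **Allometry**: AON uniform on a configured range; CBL, RL, TL from
  the configured linear relationships plus Gaussian noise. One subtlety
  is intrinsic: a single TL column cannot simultaneously satisfy the
  Method-1 (TL from CBL) and Method-2 (TL − CBL from AON) relationships
  exactly, so `tl_mode` selects which is generative and the other
  method's coefficients are implied; noise-free tests assert exact
  recovery of the generating and implied pairs.
* **Study stand-in**: `synthetic_study_matrix` /
  `synthetic_study_traits` produce a 21-OTU × 43-character matrix
  (states 0–3, 20% missing, 2% polymorphic, rate 0.12 per edge — shaped
  like a fossil-heavy morphological matrix) with the real taxon names,
  and a plausible-magnitude CBL table (e.g. *Physeter* 500 cm, *Kogia*
  ~40 cm, proxy flags where a real compilation would substitute a
  similar-sized relative). These are labelled synthetic throughout:
  their cell values, tree length (observed: well above the published
  100), clade structure and supports are **not** those of the published
  dataset, and the test suite's checks of the published tree statistics
  against this stand-in document the published targets rather than
  reproduce them.

## Problem sizes and determinism

Default search effort is 100 addition replicates (a replicate count the
original analysis does not report); on the 21 × 43 stand-in this
completes in seconds, and bootstrap (100 replicates × 10-replicate
searches) in about a minute. Correctness batteries use exhaustive
oracles at ≤ 8 taxa (labeling enumeration) and ≤ 7 taxa (topology
enumeration, 945 trees), 200 and 50 random instances respectively, 500
seeds for OLS bias, and 100 seeds for Mk topology recovery. Every
stochastic component takes an explicit integer seed, is recorded in the
search log, and is reproducible bit-for-bit at a fixed seed; the Python
`random` generator drives combinatorial simulation and NumPy's
`default_rng` drives numeric simulation.

## Known limitations

* Ordered/Sankoff-weighted characters, successive or implied weighting
  are out of scope (all characters unordered, as in the target study).
* Bremer collection and the MPT plateau are TBR-connected closures:
  near-optimal islands unreachable through trees within the length
  bound are missed, as in any heuristic implementation.
* Branch-length-weighted squared-change parsimony and ML/REML
  ancestral states are not implemented (the input consensus tree has no
  branch lengths).
* Phylogenetically corrected regression (PGLS) and multivariate
  partial-least-squares size estimation are out of scope; the pipeline
  is deliberately the simple bivariate OLS design usable for a
  specimen preserving a single proxy measurement.
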