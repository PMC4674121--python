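# parsimorph

Morphological maximum parsimony, clade support, and allometric
body-size estimation for fossil cetaceans.

`parsimorph` packages the computational core of a sperm-whale
(Physeteroidea) systematics study in which a fossil taxon known only
from a partial rostrum must be (a) placed phylogenetically from a
morphological character matrix and (b) assigned a body size from a
single cranial proxy. It is aimed at vertebrate palaeontologists who
want these analyses scripted, seeded and testable rather than locked
inside GUI phylogenetics software.

It provides:

* **NEXUS / Newick / trait-table I/O** — unordered multistate matrices
  with polymorphic (`{01}`, `(01)`, `0/1`) and missing (`?`) cells.
* **Parsimony scoring** — exact Fitch/Sankoff length on arbitrary
  (multifurcating) trees, per-character min/max steps, ensemble
  consistency index CI = Σm/L and retention index
  RI = (Σg − L)/(Σg − Σm).
* **Heuristic search** — random-addition starting trees + TBR
  hill-climbing with plateau swapping on tied trees, strict and
  majority-rule consensus, optional zero-length-branch collapse.
* **Clade support** — nonparametric character bootstrap and Bremer
  decay indices from successively longer trees.
* **Trait mapping** — squared-change parsimony reconstruction of a
  continuous trait (condylobasal length as a body-size proxy) with
  equal-width binning for display, plus stratigraphic-range annotation.
* **Allometry** — the two-method bivariate OLS pipeline estimating
  condylobasal length (CBL) and total length (TL) from antorbital
  notch width (AON):
  Method 1: `CBL = 2.51·AON + 2.84`, `TL = 3.4·CBL + 161`;
  Method 2: `CBL − RL = 0.634·AON + 31.2`, `TL − CBL = 6.33·AON + 31.2`
  (RL = preserved rostrum length), with coefficients refittable from a
  reference table.
* **Synthetic data** — Mk character matrices evolved on known Yule
  trees and allometric tables with known slopes/noise, so every stage
  is testable against ground truth.

## Worked example: body size from a partial rostrum

The specimen preserves the right half of the antorbital notch
(24.7 cm, doubled to a minimum AON of 49.4 cm) and 81.9 cm of rostrum:

```bash
parsimorph bodysize --aon 24.7 --half-aon --rostrum 81.9
```

```json
{
  "coefficients": "...",
  "estimates_cm": {
    "cbl_lower_cm": 126.8,
    "cbl_upper_cm": 144.4,
    "tl_lower_cm": 592.2,
    "tl_upper_cm": 488.3
  },
  "provenance": "published reference coefficients",
  "schema_version": 1
}
```

Reading: Method 1 predicts a 126.8 cm skull directly from notch width;
Method 2 corrects for rostrum proportions and gives the 144.4 cm upper
bound; feeding the unrounded Method-1 skull length into the TL
regression gives a ~5.9 m whale. The Method-2 TL value is the printed
equation evaluated literally; see `docs/methods.md` for why it differs
from the originally reported upper bound.

## Worked example: search and trait mapping

```bash
parsimorph simulate matrix --taxa 8 --chars 30 --rate 0.15 --seed 9 --out demo.nex
parsimorph search demo.nex --reps 20 --seed 1 --out mpts.nwk --consensus cons.nwk --log search.log
```

```
best length 45; 1 tree(s) retained
```

`search.log` is line-oriented JSON (one replicate per line: start
length, end length, rearrangements tried) and replayable from the
recorded seed. With a trait table (`taxon,CBL_cm` CSV; `~` marks proxy
values) the consensus can be painted with ancestral sizes:

```bash
parsimorph traits cons.nwk traits.csv --bins 6 --out annotated.nwk --table nodes.tsv
```

which writes a Newick with `[&value=...,bin=...]` comments and a
per-node TSV. `parsimorph all MATRIX TRAITS --aon ... --rostrum ...
--seed ...` chains search → consensus → bootstrap → trait mapping →
body size into one JSON summary; two runs with the same seed are
byte-identical.

The library mirrors the CLI: `heuristic_search`, `strict_consensus`,
`bootstrap_support`, `bremer_decay`, `squared_change_parsimony`,
`estimate_body_size`, `pipeline_from_data`, etc.

## File formats

* `examples/matrix_synthetic.nex` — NEXUS DATA block, curly-brace
  polymorphism, `?` missing (a synthetic stand-in matrix; the study's
  real supplementary matrix was published only as an image).
* `examples/traits_synthetic.csv` — `taxon,CBL_cm[,provenance]`.
* Newick in and out, with or without branch lengths; polytomies
  preserved.

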