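"""Readers and writers for the file formats the pipeline touches.

* NEXUS character matrices (DATA/CHARACTERS blocks).  Parsing is
  delegated to :mod:`dendropy`; the nonstandard slash polymorphism
  notation ("0/1") is normalised to the legal "{01}" form first.
  Writing uses one canonical dialect: curly-brace polymorphism, "?"
  for missing, no interleaving.
* Newick trees (read through dendropy, written by :class:`~parsimorph.tree.Tree`).
* Delimited trait tables (taxon, condylobasal length in cm, optional
  provenance column; a "~" prefix marks a proxy value).
"""

from __future__ import annotations

import csv
import io
import re

import dendropy

from .matrix import CharacterMatrix, StateSet, TraitTable
from .tree import Node, Tree


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# NEXUS character matrices
# ---------------------------------------------------------------------------

_SLASH_POLY = re.compile(r"(?<![\w./])(\d(?:/\d)+)(?![\w./])")


def _normalise_slash_polymorphism(text: str) -> str:
    """Rewrite "0/1" style cells to "{01}" (only after the MATRIX keyword)."""
    m = re.search(r"\bMATRIX\b", text, flags=re.IGNORECASE)
    if not m:
        return text
    head, tail = text[: m.end()], text[m.end() :]
    tail = _SLASH_POLY.sub(lambda g: "{" + g.group(1).replace("/", "") + "}", tail)
    return head + tail


def read_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    "{01}", "(01)" and "0/1" all become the state set {0, 1}; "?"
    becomes a missing cell carrying the full symbol set of the matrix.
    """
    prepared = _normalise_slash_polymorphism(text)
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=prepared, schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"could not parse NEXUS matrix: {exc}") from exc
    if len(dm) == 0:
        raise ParseError("NEXUS document contains no character matrix rows")

    taxa = [t.label for t in dm.taxon_namespace]
    rows: list[list[StateSet]] = []
    missing_cells: list[tuple[int, int]] = []
    for ti, taxon in enumerate(dm.taxon_namespace):
        seq = dm[taxon]
        row: list[StateSet] = []
        for ci, state in enumerate(seq):
            symbol = state.symbol
            if symbol == "?" or (symbol is None and not state.member_states):
                # placeholder; expanded to the full symbol set below
                row.append(StateSet.of(0))
                missing_cells.append((ti, ci))
                continue
            members = state.member_states or [state]
            codes = set()
            for st in members:
                sym = st.symbol
                if sym is None or not sym.isdigit():
                    raise ParseError(
                        f"undeclared or non-numeric symbol {sym!r} "
                        f"for taxon {taxon.label!r}, character {ci + 1}"
                    )
                codes.add(int(sym))
            if not codes:
                raise ParseError(
                    f"empty state set for taxon {taxon.label!r}, character {ci + 1}"
                )
            row.append(StateSet(frozenset(codes)))
        rows.append(row)

    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ParseError(f"rows differ in length: {sorted(lengths)}")

    ntax = re.search(r"NTAX\s*=\s*(\d+)", text, flags=re.IGNORECASE)
    nchar = re.search(r"NCHAR\s*=\s*(\d+)", text, flags=re.IGNORECASE)
    if ntax and int(ntax.group(1)) != len(rows):
        raise ParseError(
            f"declared NTAX={ntax.group(1)} but matrix has {len(rows)} taxa"
        )
    if nchar and int(nchar.group(1)) != len(rows[0]):
        raise ParseError(
            f"declared NCHAR={nchar.group(1)} but rows have {len(rows[0])} characters"
        )

    declared = _declared_symbols(text)
    observed = {s for row in rows for cell in row for s in cell.states}
    full = frozenset(declared | observed) if declared or observed else frozenset({0})
    for ti, ci in missing_cells:
        rows[ti][ci] = StateSet.missing(full)
    return CharacterMatrix(taxa, rows)


def _declared_symbols(text: str) -> set[int]:
    m = re.search(r'SYMBOLS\s*=\s*"([^"]*)"', text, flags=re.IGNORECASE)
    if not m:
        return set()
    return {int(c) for c in m.group(1) if c.isdigit()}


def write_nexus(matrix: CharacterMatrix) -> str:
    """Serialise a matrix in the canonical dialect (see module docstring)."""
    if matrix.n_taxa == 0:
        raise ValueError("cannot write a matrix with no taxa")
    symbols = sorted({s for row in matrix.rows for cell in row for s in cell.states})
    width = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        '  FORMAT DATATYPE=STANDARD GAP=- MISSING=? SYMBOLS="'
        + "".join(str(s) for s in symbols)
        + '";',
        "  MATRIX",
    ]
    for taxon, row in zip(matrix.taxa, matrix.rows):
        cells = []
        for cell in row:
            if cell.is_missing:
                cells.append("?")
            elif len(cell.states) == 1:
                cells.append(str(next(iter(cell.states))))
            else:
                cells.append("{" + "".join(str(s) for s in sorted(cell.states)) + "}")
        label = taxon.replace(" ", "_")
        lines.append(f"    {label:<{width}}{''.join(cells)}")
    lines += ["  ;", "END;", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def read_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree` (polytomies preserved)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"could not parse Newick tree: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    tree = Tree(convert(dtree.seed_node))
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate leaf labels: {dupes}")
    if any(not l for l in labels):
        raise ParseError("every leaf must carry a label")
    return tree


def write_newick(tree: Tree, include_lengths: bool = True) -> str:
    return tree.to_newick(include_lengths=include_lengths)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


def read_trait_table(text: str) -> TraitTable:
    """Parse a delimited (CSV/TSV) taxon → CBL table.

    Columns: taxon, CBL in cm, optional provenance ("measured"/"proxy").
    A "~" prefix on the length marks an approximate value, recorded as
    proxy provenance.
    """
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    table = TraitTable()
    for lineno, raw in enumerate(reader, start=1):
        row = [f.strip() for f in raw if f.strip() != ""]
        if not row:
            continue
        if len(row) < 2:
            raise ParseError(f"row {lineno}: expected at least 2 columns, got {row}")
        taxon, value_text = row[0], row[1]
        is_proxy = value_text.startswith("~")
        if is_proxy:
            value_text = value_text[1:].strip()
        if lineno == 1 and not _is_number(value_text):
            continue  # header row
        if not _is_number(value_text):
            raise ParseError(f"row {lineno} ({taxon!r}): non-numeric CBL {row[1]!r}")
        value = float(value_text)
        if value <= 0:
            raise ParseError(f"row {lineno} ({taxon!r}): CBL must be positive, got {value}")
        if len(row) >= 3:
            is_proxy = is_proxy or row[2].lower().startswith("prox") or row[2] == "*"
        try:
            table.add(taxon, value, is_proxy)
        except ValueError as exc:
            raise ParseError(f"row {lineno}: {exc}") from exc
    if len(table) == 0:
        raise ParseError("trait table contains no data rows")
    return table


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
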