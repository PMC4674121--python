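"""Core containers for discrete morphological character data.

A :class:`CharacterMatrix` is a taxa-by-characters grid of
:class:`StateSet` cells.  States are small non-negative integers
(0..9).  A cell holding more than one state is treated as *uncertainty*
("any one of these states, at no internal cost"), which is the standard
Fitch handling of both polymorphism notations ("{01}", "(01)", "0/1")
and missing data ("?", which expands to the full symbol set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class StateSet:
    """A nonempty set of candidate states for one matrix cell."""

    states: frozenset[int]
    is_missing: bool = False

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("StateSet must be nonempty")
        for s in self.states:
            if not (0 <= int(s) <= 9):
                raise ValueError(f"state code out of range 0..9: {s}")

    @classmethod
    def of(cls, *states: int) -> "StateSet":
        return cls(frozenset(int(s) for s in states))

    @classmethod
    def missing(cls, symbols: Iterable[int]) -> "StateSet":
        return cls(frozenset(int(s) for s in symbols), is_missing=True)

    @property
    def is_polymorphic(self) -> bool:
        return len(self.states) > 1 and not self.is_missing

    def __iter__(self):
        return iter(sorted(self.states))

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, s: int) -> bool:
        return s in self.states


class CharacterMatrix:
    """An ordered taxa × characters grid of state sets.

    Parameters
    ----------
    taxa:
        Unique taxon labels, in matrix row order.  Underscores and
        spaces are interchangeable when matching labels.
    rows:
        One sequence of :class:`StateSet` per taxon; all the same length.
    char_labels:
        Optional text label per character.
    ordered_flags:
        Per-character flag; all ``False`` here (every character is
        unordered, i.e. Fitch-optimised).
    """

    def __init__(
        self,
        taxa: Sequence[str],
        rows: Sequence[Sequence[StateSet]],
        char_labels: Sequence[str] | None = None,
        ordered_flags: Sequence[bool] | None = None,
    ) -> None:
        taxa = [str(t) for t in taxa]
        if len(set(_norm_label(t) for t in taxa)) != len(taxa):
            raise ValueError("taxon labels must be unique")
        if len(rows) != len(taxa):
            raise ValueError("one row of cells required per taxon")
        if not taxa:
            raise ValueError("matrix must contain at least one taxon")
        n_chars = len(rows[0])
        for t, row in zip(taxa, rows):
            if len(row) != n_chars:
                raise ValueError(
                    f"row for {t!r} has {len(row)} cells, expected {n_chars}"
                )
        self.taxa: list[str] = list(taxa)
        self.rows: list[list[StateSet]] = [list(r) for r in rows]
        self.n_chars: int = n_chars
        self.char_labels: list[str] | None = (
            list(char_labels) if char_labels is not None else None
        )
        if self.char_labels is not None and len(self.char_labels) != n_chars:
            raise ValueError("char_labels length mismatch")
        self.ordered_flags: list[bool] = (
            list(ordered_flags) if ordered_flags is not None else [False] * n_chars
        )
        if len(self.ordered_flags) != n_chars:
            raise ValueError("ordered_flags length mismatch")

    # -- basic access ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def cell(self, taxon: str, char_index: int) -> StateSet:
        return self.rows[self.taxon_index(taxon)][char_index]

    def taxon_index(self, taxon: str) -> int:
        want = _norm_label(taxon)
        for i, t in enumerate(self.taxa):
            if _norm_label(t) == want:
                return i
        raise KeyError(f"taxon not in matrix: {taxon!r}")

    def column(self, char_index: int) -> list[StateSet]:
        return [row[char_index] for row in self.rows]

    def symbols(self) -> frozenset[int]:
        """All state codes observed anywhere in the matrix (ignoring '?')."""
        out: set[int] = set()
        for row in self.rows:
            for cell in row:
                if not cell.is_missing:
                    out |= cell.states
        return frozenset(out) or frozenset({0})

    # -- equality (used by round-trip tests) ----------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            [_norm_label(t) for t in self.taxa]
            == [_norm_label(t) for t in other.taxa]
            and self.n_chars == other.n_chars
            and all(
                a.states == b.states and a.is_missing == b.is_missing
                for ra, rb in zip(self.rows, other.rows)
                for a, b in zip(ra, rb)
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_chars} chars>"


def _norm_label(label: str) -> str:
    """Taxon-label normalisation: underscores and spaces are equivalent."""
    return label.strip().replace("_", " ")


@dataclass
class TraitTable:
    """Taxon → condylobasal length (cm), with a provenance flag.

    ``proxy`` entries are lengths borrowed from a similarly-sized
    relative rather than measured on the taxon itself.
    """

    values: dict[str, float] = field(default_factory=dict)
    proxy: dict[str, bool] = field(default_factory=dict)

    def add(self, taxon: str, value: float, is_proxy: bool = False) -> None:
        key = _norm_label(taxon)
        if key in self.values:
            raise ValueError(f"duplicate taxon in trait table: {taxon!r}")
        value = float(value)
        if not value > 0:
            raise ValueError(f"trait value for {taxon!r} must be positive: {value}")
        self.values[key] = value
        self.proxy[key] = bool(is_proxy)

    def get(self, taxon: str) -> float:
        return self.values[_norm_label(taxon)]

    def __contains__(self, taxon: str) -> bool:
        return _norm_label(taxon) in self.values

    def __len__(self) -> int:
        return len(self.values)
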