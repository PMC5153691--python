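"""Assemble per-sentence extractions into a taxon-by-character matrix.

A taxon-by-character matrix is the standard interchange table of
comparative biology: rows are taxa, columns are characters, and each cell
holds the character states stated for that taxon.  The column axis is the
full closed 42-character schema regardless of which characters fired, so
downstream consumers always see the same shape.  An empty cell means
"not stated in the description", never "absent": no imputation is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .characters import CHARACTER_IDS, CHARACTERS_BY_ID
from .values import StructuredValue


@dataclass
class TaxonCharacterMatrix:
    """Taxa × 42 characters; each cell an ordered list of structured values."""

    taxa: list[str] = field(default_factory=list)
    cells: dict[tuple[str, str], list[StructuredValue]] = field(
        default_factory=dict
    )

    def get(self, taxon: str, character_id: str) -> list[StructuredValue]:
        return self.cells.get((taxon, character_id), [])

    def add(self, taxon: str, character_id: str, value: StructuredValue) -> None:
        """Append a value, creating the row if needed and collapsing exact
        duplicates (repeated mentions are not repeated character states)."""
        if not taxon:
            raise ValueError("taxon name must be non-empty")
        if character_id not in CHARACTERS_BY_ID:
            raise KeyError(f"unknown character: {character_id!r}")
        if taxon not in self.taxa:
            self.taxa.append(taxon)
        cell = self.cells.setdefault((taxon, character_id), [])
        if value not in cell:
            cell.append(value)

    def row(self, taxon: str) -> list[list[StructuredValue]]:
        return [self.get(taxon, cid) for cid in CHARACTER_IDS]

    def n_values(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonCharacterMatrix):
            return NotImplemented
        if self.taxa != other.taxa:
            return False
        keys = {k for k, v in self.cells.items() if v}
        okeys = {k for k, v in other.cells.items() if v}
        if keys != okeys:
            return False
        return all(self.cells[k] == other.cells[k] for k in keys)


def build_matrix(
    extractions: Iterable[tuple[str, str, StructuredValue]],
) -> TaxonCharacterMatrix:
    """Collate ``(taxon, character_id, value)`` triples into a matrix.

    Rows appear in first-appearance order of taxa; within a cell, values
    keep first-occurrence order with exact duplicates collapsed.  The
    result is therefore deterministic and idempotent for a given triple
    sequence.
    """
    m = TaxonCharacterMatrix()
    for taxon, character_id, value in extractions:
        m.add(taxon, character_id, value)
    return m
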