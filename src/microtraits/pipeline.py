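"""End-to-end extraction: descriptions in, taxon-by-character matrix out.

Each description is cleaned, split into sentences and annotated; every
sentence is triaged by the classifier bank (or routed to every extractor
when no bank is supplied — the ablation mode); the per-character
extractors emit structured values; and the matrix builder collates the
(taxon, character, value) triples.  Every input taxon gets a matrix row
even when nothing was extracted for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib

from .characters import CHARACTERS, CHARACTERS_BY_ID
from .corpus_io import TaxonDescription, TermList
from .extract_categorical import (
    DEFAULT_PATTERNS,
    DependencyPattern,
    extract_categorical,
)
from .extract_numeric import (
    extract_cell_dimension,
    extract_gc_content,
    extract_growth_values,
)
from .matrix_builder import TaxonCharacterMatrix
from .predictor import ClassifierBank, predict_characters
from .preprocess import (
    AnnotatedSentence,
    DEFAULT_PARSER,
    ParserAdapter,
    annotate_description,
)
from .values import StructuredValue

logger = logging.getLogger(__name__)

_BANK_FORMAT_VERSION = 1


def save_bank(bank: ClassifierBank, path: str | Path) -> None:
    """Serialize a trained classifier bank as a versioned archive."""
    joblib.dump({"format_version": _BANK_FORMAT_VERSION, "bank": bank}, path)


def load_bank(path: str | Path) -> ClassifierBank:
    payload = joblib.load(path)
    if payload.get("format_version") != _BANK_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version in {path}")
    return payload["bank"]


@dataclass
class ExtractionPipeline:
    """The full pipeline; ``bank=None`` disables sentence triage so every
    sentence reaches every extractor (the predictor-off ablation)."""

    term_lists: dict[str, TermList] = field(default_factory=dict)
    bank: ClassifierBank | None = None
    parser: ParserAdapter = DEFAULT_PARSER
    patterns: Sequence[DependencyPattern] = DEFAULT_PATTERNS

    def extract_sentence(
        self, s: AnnotatedSentence
    ) -> dict[str, list[StructuredValue]]:
        """Structured values per character for one annotated sentence."""
        if self.bank is not None:
            selected = predict_characters(self.bank, s)
        else:
            selected = {c.id for c in CHARACTERS}
        out: dict[str, list[StructuredValue]] = {}

        def put(cid: str, values: Iterable[StructuredValue]) -> None:
            bucket = out.setdefault(cid, [])
            for v in values:
                if v not in bucket:
                    bucket.append(v)

        for char in CHARACTERS:
            if char.id not in selected:
                continue
            if char.extractor == "gc":
                put(char.id, extract_gc_content(s))
            elif char.extractor.startswith("dimension:"):
                put(char.id,
                    extract_cell_dimension(s, char.extractor.split(":")[1]))
            elif char.extractor.startswith("triplet:"):
                put(char.id, extract_growth_values(s, char.id))
            else:
                routed = extract_categorical(
                    s, char, self.term_lists, self.patterns
                )
                for cid, values in routed.items():
                    put(cid, values)
        return {cid: vs for cid, vs in out.items() if vs}

    def extract_description(
        self, desc: TaxonDescription
    ) -> list[tuple[str, str, StructuredValue]]:
        triples: list[tuple[str, str, StructuredValue]] = []
        for s in annotate_description(desc.paragraphs, desc.taxon_name,
                                      self.parser):
            for cid, values in self.extract_sentence(s).items():
                triples.extend((desc.taxon_name, cid, v) for v in values)
        return triples

    def run(
        self, descriptions: Iterable[TaxonDescription]
    ) -> TaxonCharacterMatrix:
        m = TaxonCharacterMatrix()
        for desc in descriptions:
            if desc.taxon_name not in m.taxa:
                m.taxa.append(desc.taxon_name)
            for taxon, cid, value in self.extract_description(desc):
                m.add(taxon, cid, value)
        return m
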