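"""On-disk artifacts: descriptions, term lists, matrices, training data.

Two description formats are accepted.  The XML dialect wraps each
description in a child of the root element, with publication metadata
(author/title/date) on a ``meta`` element, the taxon name in a ``taxon``
element and the description paragraphs in one or more ``text`` elements:

.. code-block:: xml

    <descriptions>
      <description>
        <meta author="..." title="..." date="..."/>
        <taxon>Gracilimonas tropica</taxon>
        <text>Cells are 0.3–0.5 μm in diameter.</text>
      </description>
    </descriptions>

The TSV dialect is simply ``taxon<TAB>description`` per line.  Similar or
repeated descriptions are deliberately not deduplicated — they may
represent distinct taxon concepts.

Matrices are UTF-8 CSV with a ``Taxon`` column followed by the 42
character display names; multiple values in a cell are joined with
``" # "``.  Term lists are one plain-text file per character id, one term
per line, ``#`` comments allowed.  Training instances are
``sentence<TAB>character_id`` TSV.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from lxml import etree

from .characters import CHARACTER_IDS, CHARACTERS_BY_ID, DISPLAY_NAMES
from .matrix_builder import TaxonCharacterMatrix
from .values import (  # noqa: F401  (re-exported: part of the I/O surface)
    StructuredValue,
    parse_structured_value,
    serialize_structured_value,
)

logger = logging.getLogger(__name__)

VALUE_JOIN = " # "


@dataclass
class TaxonDescription:
    """One taxon's metadata plus description paragraphs."""

    taxon_name: str
    paragraphs: list[str]
    author: str = ""
    title: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        if not self.taxon_name.strip():
            raise ValueError("taxon_name must be non-empty")
        if not self.paragraphs:
            raise ValueError(f"description of {self.taxon_name!r} has no paragraphs")


@dataclass(frozen=True)
class TrainingInstance:
    """One sentence paired with one character label."""

    sentence_text: str
    character_id: str


@dataclass
class TermList:
    """Knowledge-base term list for one character."""

    character_id: str
    terms: frozenset[str] = frozenset()
    source: str = "manual"

    @staticmethod
    def normalize(term: str) -> str:
        return " ".join(term.lower().split())

    @classmethod
    def from_terms(cls, character_id: str, terms: Iterable[str],
                   source: str = "manual") -> "TermList":
        norm = {cls.normalize(t) for t in terms}
        norm.discard("")
        return cls(character_id, frozenset(norm), source)


# ---------------------------------------------------------------------------
# descriptions


def read_descriptions(path: str | Path, format: str = "auto") -> list[TaxonDescription]:
    """Read taxonomic descriptions from XML or TSV, preserving file order."""
    path = Path(path)
    if format == "auto":
        if path.suffix.lower() == ".xml":
            format = "xml"
        elif path.suffix.lower() in (".tsv", ".txt"):
            format = "tsv"
        else:
            head = path.read_text(encoding="utf-8", errors="replace").lstrip()[:1]
            format = "xml" if head == "<" else "tsv"
    if format == "xml":
        return _read_descriptions_xml(path)
    if format == "tsv":
        return _read_descriptions_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_descriptions_xml(path: Path) -> list[TaxonDescription]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed XML in {path}: {e}") from e
    out: list[TaxonDescription] = []
    for elem in tree.getroot():
        if not isinstance(elem.tag, str):  # skip comments/PIs
            continue
        meta = elem.find("meta")
        taxon_el = elem.find("taxon")
        taxon = (taxon_el.text or "").strip() if taxon_el is not None else ""
        if not taxon:
            raise ValueError(
                f"{path}: description element at line {elem.sourceline} "
                "has an empty taxon name"
            )
        paragraphs = [
            (t.text or "").strip() for t in elem.findall("text")
            if (t.text or "").strip()
        ]
        out.append(TaxonDescription(
            taxon_name=taxon,
            paragraphs=paragraphs,
            author=meta.get("author", "") if meta is not None else "",
            title=meta.get("title", "") if meta is not None else "",
            date=meta.get("date", "") if meta is not None else "",
        ))
    return out


def _read_descriptions_tsv(path: Path) -> list[TaxonDescription]:
    out: list[TaxonDescription] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            taxon, _, text = line.partition("\t")
            if not taxon.strip():
                raise ValueError(f"{path}:{lineno}: empty taxon name")
            if not text.strip():
                raise ValueError(f"{path}:{lineno}: empty description")
            out.append(TaxonDescription(taxon_name=taxon.strip(),
                                        paragraphs=[text.strip()]))
    return out


def write_descriptions_xml(descriptions: Iterable[TaxonDescription],
                           path: str | Path) -> None:
    root = etree.Element("descriptions")
    for d in descriptions:
        el = etree.SubElement(root, "description")
        etree.SubElement(el, "meta", author=d.author, title=d.title, date=d.date)
        etree.SubElement(el, "taxon").text = d.taxon_name
        for p in d.paragraphs:
            etree.SubElement(el, "text").text = p
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, encoding="utf-8",
                       xml_declaration=True)
    )


# ---------------------------------------------------------------------------
# term lists


def load_term_lists(directory: str | Path) -> dict[str, TermList]:
    """Load per-character term-list files; characters without a file get an
    empty list.  Files whose stem is not a known character id are skipped
    with a warning."""
    directory = Path(directory)
    lists = {cid: TermList(cid) for cid in CHARACTER_IDS}
    if directory.is_dir():
        for f in sorted(directory.glob("*.txt")):
            cid = f.stem
            if cid not in CHARACTERS_BY_ID:
                warnings.warn(f"skipping term list for unknown character {cid!r}")
                continue
            terms = []
            for line in f.read_text(encoding="utf-8").splitlines():
                line = line.split("#", 1)[0].strip()
                if line:
                    terms.append(line)
            lists[cid] = TermList.from_terms(cid, terms)
    return lists


def write_term_lists(lists: dict[str, TermList], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid, tl in lists.items():
        if tl.terms:
            (directory / f"{cid}.txt").write_text(
                "\n".join(sorted(tl.terms)) + "\n", encoding="utf-8"
            )


# ---------------------------------------------------------------------------
# training instances


def read_training_instances(path: str | Path) -> list[TrainingInstance]:
    out: list[TrainingInstance] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            sentence, _, cid = line.rpartition("\t")
            if not sentence or cid not in CHARACTERS_BY_ID:
                raise ValueError(f"{path}:{lineno}: bad training instance")
            out.append(TrainingInstance(sentence, cid))
    return out


def write_training_instances(instances: Iterable[TrainingInstance],
                             path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(f"{inst.sentence_text}\t{inst.character_id}\n")


# ---------------------------------------------------------------------------
# matrices


def write_matrix(m: TaxonCharacterMatrix, path: str | Path) -> None:
    """Write a matrix as UTF-8 CSV (``Taxon`` + 42 display-name columns)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["Taxon", *DISPLAY_NAMES])
        for taxon in m.taxa:
            row = [taxon]
            for cid in CHARACTER_IDS:
                row.append(VALUE_JOIN.join(
                    serialize_structured_value(v) for v in m.get(taxon, cid)
                ))
            writer.writerow(row)


def read_matrix(path: str | Path) -> TaxonCharacterMatrix:
    """Read a matrix CSV written by :func:`write_matrix`."""
    m = TaxonCharacterMatrix()
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[0] != "Taxon":
            raise ValueError(f"{path}: missing matrix header")
        if tuple(header[1:]) != DISPLAY_NAMES:
            raise ValueError(f"{path}: header does not match the character schema")
        for row in reader:
            if not row:
                continue
            taxon = row[0]
            if not taxon.strip():
                raise ValueError(f"{path}: empty taxon name in matrix row")
            if taxon not in m.taxa:
                m.taxa.append(taxon)
            for cid, cell in zip(CHARACTER_IDS, row[1:]):
                if not cell:
                    continue
                kind = CHARACTERS_BY_ID[cid].value_kind
                for chunk in cell.split(VALUE_JOIN):
                    if chunk.strip():
                        m.add(taxon, cid,
                              parse_structured_value(chunk, kind))
    return m
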