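"""Text cleaning, sentence splitting, and sentence annotation.

Descriptions arrive as paragraphs of prose.  Before extraction each
paragraph is (1) cleaned — predefined XML entities replaced, stray
symbols outside a retained punctuation whitelist removed, whitespace
collapsed; (2) split into sentences with an abbreviation-aware splitter
that never breaks at decimals, ranges, or domain abbreviations such as
"sp." and "approx."; and (3) annotated with tokens, Penn-style POS tags
and a small set of dependency edges.

Annotation goes through a pluggable parser-adapter contract — three pure
functions ``tokenize``, ``pos_tag`` and ``parse_dependencies`` — so that
a full statistical parser can be substituted.  The shipped
:class:`FallbackParser` is a deterministic rule-based adapter (regex
tokenizer, lexicon + suffix tagger, pattern-matched dependencies for the
passive/active verb constructions the extractors rely on).  It requires
no model downloads and gives byte-identical annotations across runs,
which makes the extraction rules and every test reproducible; parse
quality on arbitrary prose is of course below that of a trained parser.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Protocol

Dependency = tuple[int, int, str]  # (governor index, dependent index, label)


class AnnotationError(ValueError):
    """Raised when a sentence cannot be annotated."""


class ParserAdapter(Protocol):
    """Contract every parser backend must satisfy."""

    def tokenize(self, text: str) -> list[str]: ...

    def pos_tag(self, tokens: list[str]) -> list[str]: ...

    def parse_dependencies(
        self, tokens: list[str], tags: list[str]
    ) -> frozenset[Dependency]: ...


@dataclass(frozen=True)
class AnnotatedSentence:
    """A cleaned sentence with tokens, POS tags and dependency edges."""

    text: str
    taxon_name: str
    tokens: tuple[str, ...]
    pos_tags: tuple[str, ...]
    dependencies: frozenset[Dependency]
    sentence_index: int = 0

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise AnnotationError("empty sentence")
        if len(self.tokens) != len(self.pos_tags):
            raise AnnotationError("token/tag length mismatch")
        n = len(self.tokens)
        for gov, dep, _ in self.dependencies:
            if not (0 <= gov < n and 0 <= dep < n):
                raise AnnotationError("dependency index out of range")


# ---------------------------------------------------------------------------
# cleaning

_ENTITIES = {
    "&lt;": "<",
    "&gt;": ">",
    "&quot;": '"',
    "&apos;": "'",
    "&amp;": "&",
}

# Encoding repair for near-equivalent codepoints seen in extracted text.
_CHAR_REPAIRS = str.maketrans({
    "µ": "μ",   # micro sign -> Greek mu
    "−": "-",   # minus sign -> hyphen
    "˚": "°",   # ring above -> degree
    "—": "–",   # em dash -> en dash
    "‘": "'", "’": "'",
    "“": '"', "”": '"',
})

# Retained characters: letters, digits, whitespace, and the punctuation
# the downstream rules need (incl. μ ° – │ % #).
_DISALLOWED = re.compile(r"[^\w\s.,;:()\[\]%°μ–\-/+<>='\"│#&]|_")
_WS = re.compile(r"\s+")


def clean_text(raw: str) -> str:
    """Normalize raw text.  Total and idempotent."""
    s = raw
    while True:
        t = s
        for ent, ch in _ENTITIES.items():
            t = t.replace(ent, ch)
        if t == s:
            break
        s = t
    s = s.translate(_CHAR_REPAIRS)
    s = _DISALLOWED.sub("", s)
    return _WS.sub(" ", s).strip()


# ---------------------------------------------------------------------------
# sentence splitting

with resources.files(__package__).joinpath("data/abbreviations.txt").open(
    encoding="utf-8"
) as _fh:
    ABBREVIATIONS = frozenset(
        line.strip().lower()
        for line in _fh
        if line.strip() and not line.startswith("#")
    )

_TERMINAL = re.compile(r"[.!?]+")
_NEXT_SENTENCE = re.compile(r"\s+[\"'(]?[A-Z0-9μ]")


def split_sentences(paragraph: str) -> list[str]:
    """Split a cleaned paragraph into sentences.

    A terminal-punctuation run ends a sentence only when followed by
    whitespace and an upper-case/numeric sentence opener, and the word
    before it is neither a known abbreviation nor a single letter
    (initials).  Decimals and en-dash ranges contain no whitespace after
    the dot and are therefore never split.
    """
    text = paragraph.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for m in _TERMINAL.finditer(text):
        if not _NEXT_SENTENCE.match(text, m.end()):
            continue
        before = text[start:m.start()].split()
        last = before[-1].lower() if before else ""
        if (last + text[m.start():m.end()]) in ABBREVIATIONS:
            continue
        if len(last) == 1 and last.isalpha():
            continue
        chunk = text[start:m.end()].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# fallback parser adapter

_NUMBER = r"\d+(?:\.\d+)?"
NUMERIC_TOKEN = re.compile(rf"{_NUMBER}(?:[–-]{_NUMBER})?$")

_TOKEN = re.compile(
    rf"mol\s?%"
    rf"|{_NUMBER}-[^\W\d_][\w-]*"            # chemical names like 5-ketogluconate
    rf"|{_NUMBER}(?:\s?[–-]\s?{_NUMBER})?"   # numbers and ranges
    rf"|[^\W\d_][\w'+/-]*\+?"                # words, hyphenated compounds, Mg2+
    rf"|[^\w\s]",                            # punctuation
)

with resources.files(__package__).joinpath("data/pos_lexicon.json").open(
    encoding="utf-8"
) as _fh:
    _LEXICON_RAW: dict[str, list[str]] = json.load(_fh)
_LEXICON: dict[str, str] = {
    w: tag for tag, words in _LEXICON_RAW.items() for w in words
}

_JJ_SUFFIX = re.compile(
    r".*(ous|ive|ic|al|ile|ar|oid|ular|form|like|shaped|philic|negative|positive)$"
)
_BE = frozenset({"is", "are", "was", "were", "be", "been", "being"})
_NOUN_TAGS = frozenset({"NN", "NNS", "NNP"})
_NMOD_PREPS = frozenset({"from", "to", "for", "on", "in", "by", "with", "of"})


class FallbackParser:
    """Deterministic rule-based adapter: regex tokenizer, lexicon+suffix
    POS tagger, and pattern dependencies for passive ("Acid is produced
    from glucose") and simple active verb constructions."""

    name = "fallback"

    def tokenize(self, text: str) -> list[str]:
        tokens = []
        for m in _TOKEN.finditer(text):
            tok = m.group(0)
            tok = re.sub(r"mol\s%", "mol%", tok)
            tok = re.sub(r"\s?([–-])\s?", r"\1", tok) if NUMERIC_TOKEN.match(
                tok.replace(" ", "")
            ) else tok
            tokens.append(tok)
        return tokens

    def pos_tag(self, tokens: list[str]) -> list[str]:
        tags: list[str] = []
        for i, tok in enumerate(tokens):
            low = tok.lower()
            if NUMERIC_TOKEN.match(tok):
                tags.append("CD")
            elif not re.search(r"\w", tok):
                tags.append(tok)  # punctuation tags itself
            elif low in _LEXICON:
                tags.append(_LEXICON[low])
            elif low.startswith("non-"):
                tags.append("JJ")
            elif low.endswith("ly"):
                tags.append("RB")
            elif low.endswith("ed"):
                tags.append("VBN")
            elif low.endswith("ing"):
                tags.append("VBG")
            elif _JJ_SUFFIX.match(low):
                tags.append("JJ")
            elif i > 0 and tok[:1].isupper():
                tags.append("NNP")
            elif low.endswith("s") and not low.endswith(("ss", "us", "is")):
                tags.append("NNS")
            else:
                tags.append("NN")
        return tags

    def parse_dependencies(
        self, tokens: list[str], tags: list[str]
    ) -> frozenset[Dependency]:
        deps: set[Dependency] = set()
        lows = [t.lower() for t in tokens]
        for i, low in enumerate(lows):
            if low in _BE and tags[i] in ("VBZ", "VBP", "VBD"):
                # passive: BE (+RB)? VBN
                j = i + 1
                while j < len(tokens) and tags[j] == "RB":
                    j += 1
                if j < len(tokens) and tags[j] == "VBN":
                    subj = self._last_noun_before(tags, i)
                    if subj is not None:
                        deps.add((j, subj, "nsubjpass"))
                    deps.update(self._nmods(tokens, tags, lows, j))
            elif tags[i] in ("VBZ", "VBP") and low not in _BE:
                subj = self._last_noun_before(tags, i)
                if subj is not None:
                    deps.add((i, subj, "nsubj"))
                obj = self._first_noun_after(tags, lows, i)
                if obj is not None:
                    deps.add((i, obj, "dobj"))
                deps.update(self._nmods(tokens, tags, lows, i))
        return frozenset(deps)

    @staticmethod
    def _last_noun_before(tags: list[str], i: int) -> int | None:
        for j in range(i - 1, -1, -1):
            if tags[j] in _NOUN_TAGS:
                return j
            if tags[j] in (",", ";", ".", "VBZ", "VBP", "VBD"):
                break
        return None

    @staticmethod
    def _first_noun_after(tags: list[str], lows: list[str], i: int) -> int | None:
        for j in range(i + 1, len(tags)):
            if lows[j] in _NMOD_PREPS or tags[j] in (",", ";", "."):
                return None
            if tags[j] in _NOUN_TAGS:
                return FallbackParser._noun_run_head(tags, j)
        return None

    @staticmethod
    def _noun_run_head(tags: list[str], j: int) -> int:
        # the head of a noun compound is its last noun ("sea salts" -> salts)
        while j + 1 < len(tags) and tags[j + 1] in _NOUN_TAGS:
            j += 1
        return j

    @staticmethod
    def _nmods(tokens, tags, lows, verb: int) -> set[Dependency]:
        deps: set[Dependency] = set()
        for j in range(verb + 1, len(tokens)):
            if tags[j] in (";", "."):
                break
            if lows[j] in _NMOD_PREPS and tags[j] == "IN":
                for k in range(j + 1, len(tokens)):
                    if tags[k] in _NOUN_TAGS:
                        deps.add((verb,
                                  FallbackParser._noun_run_head(tags, k),
                                  "nmod"))
                        break
                    if tags[k] not in ("DT", "JJ", "VBN", "RB", "CD"):
                        break
        return deps


DEFAULT_PARSER = FallbackParser()

PARSERS: dict[str, ParserAdapter] = {"fallback": DEFAULT_PARSER}


def get_parser(name: str) -> ParserAdapter:
    try:
        return PARSERS[name]
    except KeyError:
        raise KeyError(
            f"unknown parser {name!r}; registered: {sorted(PARSERS)}"
        ) from None


def annotate_sentence(
    text: str,
    taxon: str = "",
    parser: ParserAdapter = DEFAULT_PARSER,
    sentence_index: int = 0,
) -> AnnotatedSentence:
    """Tokenize, tag and dependency-parse one cleaned sentence."""
    if not text.strip():
        raise AnnotationError("cannot annotate an empty sentence")
    try:
        tokens = parser.tokenize(text)
        tags = parser.pos_tag(tokens)
        deps = parser.parse_dependencies(tokens, tags)
    except AnnotationError:
        raise
    except Exception as e:  # adapter failure carries the sentence text
        raise AnnotationError(f"annotation failed for {text!r}: {e}") from e
    return AnnotatedSentence(
        text=text,
        taxon_name=taxon,
        tokens=tuple(tokens),
        pos_tags=tuple(tags),
        dependencies=deps,
        sentence_index=sentence_index,
    )


def annotate_description(
    paragraphs: Iterable[str],
    taxon: str,
    parser: ParserAdapter = DEFAULT_PARSER,
) -> list[AnnotatedSentence]:
    """Clean, split and annotate all paragraphs of one description."""
    out: list[AnnotatedSentence] = []
    idx = 0
    for para in paragraphs:
        for sent in split_sentences(clean_text(para)):
            out.append(annotate_sentence(sent, taxon, parser, idx))
            idx += 1
    return out
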