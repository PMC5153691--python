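"""String-valued character extraction.

Categorical character states ("Gram-negative", "short chains",
"tetracycline") are recognized by combining:

* noun-phrase chunking over POS tags, with coordinated siblings
  ("chloramphenicol, streptomycin and kanamycin") grouped together;
* whole-word term matching of knowledge-base terms inside a phrase —
  the *full* phrase is extracted, not the bare term, so "chains" in the
  term list yields the value "short chains";
* coordination expansion: once any conjunct of a coordinated list
  matches, every conjunct becomes a value;
* declarative dependency patterns, e.g. the passive "X is produced from
  Y" in which the subject is a fermentation product and the object of
  "from" a fermentation substrate;
* polarity routing: candidates inside a negation scope ("… but not
  mannitol, gluconate and malate") move to the paired "not used"
  character, while partnerless characters keep the negated wording
  verbatim ("non-motile", "No spores").

Cross-phrase values ("rod-shaped with slightly irregular sides and
pointed ends") are not merged; one phrase is one value.
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .characters import CharacterDef, CHARACTERS_BY_ID
from .corpus_io import TermList
from .preprocess import AnnotatedSentence
from .values import StructuredValue

_NOUN_TAGS = frozenset({"NN", "NNS", "NNP"})
_NP_INNER = frozenset({"JJ", "VBN", "NN", "NNS", "NNP"})
_COORD_TOKENS = frozenset({",", "and", "or", "nor", "neither", "either"})
_STRIP_DETS = frozenset({"a", "an", "the", "some", "most", "several"})
_NEG_TOKENS = frozenset({"not", "no", "neither", "nor", "without"})
_VERB_TAGS = frozenset({"VBZ", "VBP", "VBD", "MD"})


@dataclass(frozen=True)
class NounPhrase:
    """A chunked noun phrase with its head and coordination group."""

    text: str                    # phrase with leading article stripped
    head_index: int              # token index of the head noun
    span: tuple[int, int]        # token range [start, end)
    coordination_group: int | None = None


def _whole_word(term: str) -> re.Pattern[str]:
    return re.compile(rf"(?<![\w-]){re.escape(term)}(?![\w-])", re.IGNORECASE)


# ---------------------------------------------------------------------------
# chunking


def chunk_noun_phrases(s: AnnotatedSentence) -> list[NounPhrase]:
    """Maximal ``DT? (JJ|VBN|NN|NNS)* (NN|NNS|NNP)`` chunks with
    comma/and/or-separated siblings sharing a coordination group."""
    chunks: list[tuple[int, int, int]] = []  # (start, end, head)
    i = 0
    n = len(s.tokens)

    def inner(k: int) -> bool:
        # degree adverbs ("slightly brown colonies") belong to the phrase;
        # the negation cue does not
        return s.pos_tags[k] in _NP_INNER or (
            s.pos_tags[k] == "RB" and s.tokens[k].lower() != "not"
        )

    while i < n:
        tag = s.pos_tags[i]
        if tag == "DT" or inner(i):
            j = i + 1 if tag == "DT" else i
            while j < n and inner(j):
                j += 1
            # trim back to the last noun; skip if the run holds none
            head = None
            for k in range(j - 1, i - 1, -1):
                if s.pos_tags[k] in _NOUN_TAGS:
                    head = k
                    break
            if head is not None:
                chunks.append((i, head + 1, head))
                i = head + 1
                continue
            i = j if j > i else i + 1
        else:
            i += 1

    phrases: list[NounPhrase] = []
    group_ids: list[int | None] = [None] * len(chunks)
    next_group = 0
    for idx in range(1, len(chunks)):
        gap = [t.lower() for t in s.tokens[chunks[idx - 1][1]:chunks[idx][0]]]
        if gap and all(t in _COORD_TOKENS for t in gap):
            if group_ids[idx - 1] is None:
                group_ids[idx - 1] = next_group
                next_group += 1
            group_ids[idx] = group_ids[idx - 1]
    for (start, end, head), gid in zip(chunks, group_ids):
        toks = list(s.tokens[start:end])
        if toks and toks[0].lower() in _STRIP_DETS:
            toks = toks[1:]
        if not toks:
            continue
        phrases.append(NounPhrase(
            text=" ".join(toks), head_index=head, span=(start, end),
            coordination_group=gid,
        ))
    return phrases


# ---------------------------------------------------------------------------
# term matching


def term_match(p: NounPhrase, tl: TermList) -> StructuredValue | None:
    """Whole-word match of any list term inside the phrase; the full
    phrase (pre-modifiers included) is the value.  Longest term wins."""
    for term in sorted(tl.terms, key=lambda t: (-len(t), t)):
        if _whole_word(term).search(p.text):
            return StructuredValue(main_value=p.text)
    return None


def sentence_term_match(
    s: AnnotatedSentence, tl: TermList
) -> list[StructuredValue]:
    """Direct term-in-sentence matching for characters whose states occur
    verbatim (e.g. "motile", "Gram-negative", "convex").

    Longer terms claim their span first, so "non-motile" blocks a nested
    "motile" match.  A preceding "-ly" adverb is captured as the
    modifier ("Strictly anaerobic" -> strictly │ anaerobic) and a
    preceding "not" fills the negation field.
    """
    taken: list[tuple[int, int]] = []
    found: list[tuple[int, StructuredValue]] = []
    for term in sorted(tl.terms, key=lambda t: (-len(t), t)):
        for m in _whole_word(term).finditer(s.text):
            if any(a < m.end() and m.start() < b for a, b in taken):
                continue
            taken.append((m.start(), m.end()))
            before = s.text[:m.start()].rstrip()
            words = before.split()
            negation = modifier = ""
            if words:
                last = words[-1]
                if last.lower() in ("not", "no"):
                    negation = last.lower()
                elif last.lower().endswith("ly"):
                    modifier = last.lower()
                    if len(words) >= 2 and words[-2].lower() == "not":
                        negation = "not"
            found.append((m.start(), StructuredValue(
                main_value=m.group(0), negation=negation, modifier=modifier,
            )))
    return [v for _, v in sorted(found, key=lambda t: t[0])]


# ---------------------------------------------------------------------------
# coordination expansion


def _expand_phrases(
    phrases: Sequence[NounPhrase], matched: Iterable[NounPhrase]
) -> list[NounPhrase]:
    matched = list(matched)
    hit_groups = {
        p.coordination_group for p in matched if p.coordination_group is not None
    }
    out = []
    seen = set()
    for p in phrases:
        if p in matched or p.coordination_group in hit_groups:
            if p.span not in seen:
                seen.add(p.span)
                out.append(p)
    return out


def expand_coordination(
    phrases: Sequence[NounPhrase], matched: Iterable[NounPhrase]
) -> set[StructuredValue]:
    """All phrases of any coordination group containing a matched phrase
    become values; monotone and idempotent, result ⊇ matched."""
    return {
        StructuredValue(main_value=p.text)
        for p in _expand_phrases(phrases, matched)
    }


# ---------------------------------------------------------------------------
# dependency patterns


@dataclass(frozen=True)
class DependencyPattern:
    """A declarative trigger + role map relation-extraction rule."""

    name: str
    trigger: str                      # verb/adjective lemma
    role_map: dict[str, str] = field(hash=False)
    voice: str = "passive"            # passive | active | adjective
    particle: str = ""                # preposition introducing pobj role
    requires_particle: str = ""
    forbids_particle: str = ""
    context: str = ""                 # substring that must occur in sentence
    filter_termlist: bool = False

    def __post_init__(self) -> None:
        if not self.role_map:
            raise ValueError(f"pattern {self.name} has an empty role_map")

    def lemma_forms(self) -> frozenset[str]:
        t = self.trigger
        return frozenset({t, t + "s", t + "es", t + "d", t + "ed", t + "ing"})


def _load_patterns() -> tuple[DependencyPattern, ...]:
    with resources.files(__package__).joinpath("data/patterns.json").open(
        encoding="utf-8"
    ) as fh:
        raw = json.load(fh)
    return tuple(DependencyPattern(**entry) for entry in raw)


DEFAULT_PATTERNS: tuple[DependencyPattern, ...] = _load_patterns()


@dataclass(frozen=True)
class PatternExtraction:
    value: StructuredValue
    high_confidence: bool = False


def _phrase_at(phrases: Sequence[NounPhrase], idx: int) -> NounPhrase | None:
    for p in phrases:
        if p.span[0] <= idx < p.span[1]:
            return p
    return None


def _trigger_indices(s: AnnotatedSentence, pat: DependencyPattern) -> list[int]:
    forms = pat.lemma_forms()
    out = []
    for i, tok in enumerate(s.tokens):
        if tok.lower() not in forms:
            continue
        tag = s.pos_tags[i]
        if pat.voice == "passive" and tag != "VBN":
            continue
        if pat.voice == "active" and tag not in ("VBZ", "VBP"):
            continue
        out.append(i)
    return out


def _has_particle(s: AnnotatedSentence, verb: int, particle: str) -> bool:
    for j in range(verb + 1, len(s.tokens)):
        if s.pos_tags[j] in (";", "."):
            return False
        if s.tokens[j].lower() == particle:
            return True
    return False


def _negated_trigger(s: AnnotatedSentence, trigger: int) -> bool:
    for j in range(trigger - 1, -1, -1):
        if s.pos_tags[j] in (";", ","):
            break
        if s.tokens[j].lower() in ("not", "no", "neither"):
            return True
    return False


def apply_dependency_pattern(
    s: AnnotatedSentence,
    pat: DependencyPattern,
    term_lists: dict[str, TermList] | None = None,
) -> dict[str, list[PatternExtraction]]:
    """Apply one pattern; role fillers are the noun phrases headed by the
    tokens bearing the mapped relations, with coordination expansion.

    A filler that also term-matches the mapped character's list is
    flagged high-confidence.  When the trigger is negated ("no acid is
    produced from …") each role is rerouted to the character's polarity
    partner; roles without a partner are dropped.
    """
    result: dict[str, list[PatternExtraction]] = defaultdict(list)
    if pat.context and pat.context.lower() not in s.text.lower():
        return dict(result)
    phrases = chunk_noun_phrases(s)
    for trig in _trigger_indices(s, pat):
        if pat.requires_particle and not _has_particle(s, trig, pat.requires_particle):
            continue
        if pat.forbids_particle and _has_particle(s, trig, pat.forbids_particle):
            continue
        negated = _negated_trigger(s, trig)
        for relation, char_id in pat.role_map.items():
            target = char_id
            if negated:
                partner = CHARACTERS_BY_ID[char_id].polarity_partner
                if partner is None:
                    continue
                target = partner
            fillers: list[NounPhrase] = []
            if relation == "pobj":
                fillers = _pobj_fillers(s, trig, pat.particle, phrases)
            else:
                for gov, dep, label in s.dependencies:
                    if gov == trig and label == relation:
                        p = _phrase_at(phrases, dep)
                        if p is not None:
                            fillers.append(p)
            fillers = _expand_phrases(phrases, fillers)
            tl = (term_lists or {}).get(char_id)
            for p in fillers:
                text = p.text
                if negated:
                    first, _, rest = text.partition(" ")
                    if first.lower() in ("no", "not") and rest:
                        text = rest
                stripped = NounPhrase(text, p.head_index, p.span,
                                      p.coordination_group)
                high = bool(tl and tl.terms and term_match(stripped, tl))
                if pat.filter_termlist and not high:
                    continue
                result[target].append(PatternExtraction(
                    StructuredValue(main_value=text), high_confidence=high
                ))
    return dict(result)


def _pobj_fillers(
    s: AnnotatedSentence, trig: int, particle: str,
    phrases: Sequence[NounPhrase],
) -> list[NounPhrase]:
    """First noun phrase after ``trigger particle`` (its coordination
    group is expanded by the caller)."""
    for j in range(trig + 1, len(s.tokens)):
        if s.pos_tags[j] in (";", "."):
            return []
        if s.tokens[j].lower() == particle:
            for p in phrases:
                if p.span[0] > j:
                    return [p]
            return []
    return []


# ---------------------------------------------------------------------------
# polarity routing


def _negation_scopes(s: AnnotatedSentence) -> list[tuple[int, int]]:
    """Token ranges governed by a negation cue: from the cue to the end
    of its coordination list or clause (the next finite verb, ';' or
    sentence end).  A verb directly after the cue is the negated
    predicate and stays inside the scope."""
    scopes = []
    for i, tok in enumerate(s.tokens):
        if tok.lower() not in _NEG_TOKENS:
            continue
        j = i + 1
        if j < len(s.tokens) and (s.pos_tags[j] in _VERB_TAGS
                                  or s.pos_tags[j].startswith("VB")):
            j += 1
        while j < len(s.tokens):
            tag = s.pos_tags[j]
            low = s.tokens[j].lower()
            if tag in (";", ".") or tag in _VERB_TAGS:
                break
            if low in ("and", "but") and j + 1 < len(s.tokens) and (
                s.pos_tags[j + 1] in _VERB_TAGS
            ):
                break
            j += 1
        scopes.append((i, j))
    return scopes


def route_polarity(
    s: AnnotatedSentence,
    candidates: Sequence[tuple[NounPhrase, StructuredValue]],
    char: CharacterDef,
) -> dict[str, list[StructuredValue]]:
    """Split candidate values of ``char`` by negation scope.

    In-scope candidates go to the polarity partner when one exists
    ("… but not mannitol" → the Not-Used character).  For partnerless
    characters the negated wording is kept: a "No"-determiner phrase is
    emitted verbatim ("No spores"), any other cue fills the negation
    field ("not │ motile").
    """
    scopes = _negation_scopes(s)
    out: dict[str, list[StructuredValue]] = defaultdict(list)
    # for the negative member of a pair ("… Not Used") the roles flip:
    # negated candidates are its own, positive ones belong to the partner
    negative_member = char.polarity_partner is not None and "not_" in char.id
    positive_target = char.polarity_partner if negative_member else char.id

    def in_scope(p: NounPhrase) -> bool:
        return any(a <= p.span[0] < b or a < p.span[1] <= b for a, b in scopes)

    for phrase, value in candidates:
        negated = in_scope(phrase) or phrase.text.lower().startswith(("no ", "not "))
        if not negated:
            out[positive_target].append(value)
        elif char.polarity_partner is not None:
            text = value.main_value
            first, _, rest = text.partition(" ")
            if first.lower() in ("no", "not") and rest:
                text = rest
            negative_target = char.id if negative_member else char.polarity_partner
            out[negative_target].append(value.replace(main_value=text))
        elif phrase.text.lower().startswith("no "):
            out[char.id].append(value)  # "No spores" kept verbatim
        else:
            out[char.id].append(value.replace(negation="not"))
    return dict(out)


# ---------------------------------------------------------------------------
# per-character orchestration


def extract_categorical(
    s: AnnotatedSentence,
    char: CharacterDef,
    term_lists: dict[str, TermList],
    patterns: Sequence[DependencyPattern] = DEFAULT_PATTERNS,
) -> dict[str, list[StructuredValue]]:
    """All values one categorical character's extractor derives from a
    sentence, keyed by character id (polarity routing may emit under the
    partner id)."""
    out: dict[str, list[StructuredValue]] = defaultdict(list)
    tl = term_lists.get(char.id)
    # "pattern" extractors (e.g. the antibiotic characters) rely on their
    # syntactic trigger; their term list only boosts/filters pattern fillers
    if char.extractor != "pattern" and tl and tl.terms:
        if char.match_mode == "sentence":
            for v in sentence_term_match(s, tl):
                out[char.id].append(v)
        else:
            phrases = chunk_noun_phrases(s)
            matched = [p for p in phrases if term_match(p, tl)]
            candidates = [
                (p, StructuredValue(main_value=p.text))
                for p in _expand_phrases(phrases, matched)
            ]
            for cid, values in route_polarity(s, candidates, char).items():
                out[cid].extend(values)
    for pat in patterns:
        if char.id not in pat.role_map.values():
            continue
        for cid, extractions in apply_dependency_pattern(
            s, pat, term_lists
        ).items():
            for e in extractions:
                out[cid].append(e.value)
    # collapse duplicates, first occurrence wins
    for cid in list(out):
        seen: list[StructuredValue] = []
        for v in out[cid]:
            if v not in seen:
                seen.append(v)
        out[cid] = seen
    return dict(out)
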