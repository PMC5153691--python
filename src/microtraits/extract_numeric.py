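"""Numeric character extraction: %G+C, cell dimensions, growth triplets.

Thirteen of the 42 characters are numeric: genomic G+C content (mol%),
cell diameter/length/width (μm), and the minimum/optimum/maximum triplets
for growth temperature (°C), pH, and salt concentration (%, M or g l−1,
with a sub-character naming the salt).  They are extracted with
regular-expression and POS-window rules:

* G+C content: a ``CD``-tagged numeral immediately followed by ``mol%``;
* cell dimensions: a numeral whose dimension keyword ("diameter",
  "long"/"length", "wide"/"width") occurs within a 3-token window — the
  window after the numeral is the primary rule, a symmetric window
  before the numeral (for "width of 0.5–0.9 μm" phrasing) is the
  lower-priority fallback; the nearest keyword wins and a numeral feeds
  at most one dimension;
* growth triplets: a small grammar over numeric mentions classified by
  their local context — an "optim…" cue claims the optimum, "at least"
  the minimum, "up to" the maximum, and a bare range such as
  "pH 1.8–4.0" is split into minimum and maximum.  A point value with no
  cue is deliberately left unassigned (a growth observation is not
  promoted to an optimum — extraction stays true to the original
  wording).

Extracted values are post-processed by :func:`standardize_value`, which
maps unit spellings to canonical forms ("1.2–2.4 microns" → "1.2–2.4 μm")
and unifies range dashes to the en-dash.  No unit conversion is done.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from importlib import resources

from .characters import CHARACTERS_BY_ID
from .preprocess import AnnotatedSentence, NUMERIC_TOKEN
from .values import StructuredValue

logger = logging.getLogger(__name__)

_NUM = r"\d+(?:\.\d+)?"
_RANGE_RE = re.compile(rf"({_NUM})(?:\s?[–-]\s?({_NUM}))?")
_QUALIFIER_RE = re.compile(
    r"(up to|at least|about|approximately|approx\.?|ca\.?|around|over|"
    r"below|less than|more than)\s+$",
    re.IGNORECASE,
)

with resources.files(__package__).joinpath("data/units.json").open(
    encoding="utf-8"
) as _fh:
    UNIT_SYNONYMS: dict[str, list[str]] = json.load(_fh)

_UNIT_CANON: dict[str, str] = {}
for _canon, _syns in UNIT_SYNONYMS.items():
    for _s in _syns:
        _UNIT_CANON[_s.lower()] = _canon

_LENGTH_UNITS = frozenset(
    s.lower() for c in ("μm", "mm", "nm") for s in UNIT_SYNONYMS[c]
)


def standardize_unit(unit: str) -> str:
    if not unit:
        return ""
    canon = _UNIT_CANON.get(" ".join(unit.split()).lower())
    if canon is None:
        logger.info("unknown unit %r passed through", unit)
        return unit
    return canon


def normalize_range_text(text: str) -> str:
    """Unify hyphen ranges to the en-dash and drop internal spaces."""
    return re.sub(rf"({_NUM})\s?[–-]\s?({_NUM})", r"\1–\2", text.strip())


@dataclass(frozen=True)
class NumericMention:
    """One numeric value or range found in a sentence."""

    low: float
    high: float
    text: str  # normalized surface form, e.g. "33.1–34.4"
    unit: str = ""
    qualifier: str = ""
    span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"inverted range {self.text!r}")


def parse_numeric_range(text: str) -> NumericMention | None:
    """Parse ``D``, ``D–D``, and qualified forms like "up to 4 μm".

    Returns ``None`` when the input carries no numeral.
    """
    m = _RANGE_RE.search(text)
    if m is None:
        return None
    low = float(m.group(1))
    high = float(m.group(2)) if m.group(2) else low
    qual = _QUALIFIER_RE.search(text[:m.start()])
    trailing = text[m.end():].strip(" .,;")
    unit = standardize_unit(trailing) if trailing else ""
    return NumericMention(
        low=min(low, high),
        high=max(low, high),
        text=normalize_range_text(m.group(0)),
        unit=unit,
        qualifier=qual.group(1).lower() if qual else "",
        span=(m.start(), m.end()),
    )


def standardize_value(v: StructuredValue) -> StructuredValue:
    """Canonical unit spelling and en-dash ranges; idempotent."""
    return v.replace(
        main_value=normalize_range_text(v.main_value),
        unit=standardize_unit(v.unit),
    )


# ---------------------------------------------------------------------------
# %G+C


def extract_gc_content(s: AnnotatedSentence) -> list[StructuredValue]:
    """Every CD numeral immediately followed by "mol%"."""
    out = []
    for i, (tok, tag) in enumerate(zip(s.tokens, s.pos_tags)):
        if tag != "CD":
            continue
        nxt = s.tokens[i + 1] if i + 1 < len(s.tokens) else ""
        nxt2 = s.tokens[i + 2] if i + 2 < len(s.tokens) else ""
        if nxt.lower() == "mol%" or (nxt.lower() == "mol" and nxt2 == "%"):
            out.append(StructuredValue(
                main_value=normalize_range_text(tok), unit="mol%"
            ))
    return out


# ---------------------------------------------------------------------------
# cell dimensions

DIMENSION_KEYWORDS: dict[str, frozenset[str]] = {
    "diameter": frozenset({"diameter"}),
    "length": frozenset({"long", "length", "longer"}),
    "width": frozenset({"wide", "width", "wider"}),
}

_WINDOW = 3


def _dimension_candidates(s: AnnotatedSentence, i: int):
    """(dimension, direction, distance) candidates for numeral at i.

    Direction 0 = keyword after the numeral (primary rule), 1 = keyword
    before (fallback); candidates sort nearest-first, after-before on ties.
    """
    cands = []
    for dist in range(1, _WINDOW + 1):
        if i + dist < len(s.tokens):
            low = s.tokens[i + dist].lower()
            for dim, kws in DIMENSION_KEYWORDS.items():
                if low in kws:
                    cands.append((dim, 0, dist))
        if i - dist >= 0:
            low = s.tokens[i - dist].lower()
            for dim, kws in DIMENSION_KEYWORDS.items():
                if low in kws:
                    cands.append((dim, 1, dist))
    return sorted(cands, key=lambda c: (c[2], c[1]))


def extract_cell_dimension(
    s: AnnotatedSentence, dimension: str
) -> list[StructuredValue]:
    """Numeric mentions assigned to one of diameter/length/width."""
    if dimension not in DIMENSION_KEYWORDS:
        raise ValueError(f"unknown dimension {dimension!r}")
    out = []
    for i, (tok, tag) in enumerate(zip(s.tokens, s.pos_tags)):
        if tag != "CD" or not NUMERIC_TOKEN.match(tok):
            continue
        cands = _dimension_candidates(s, i)
        if not cands or cands[0][0] != dimension:
            continue
        unit = ""
        if i + 1 < len(s.tokens) and s.tokens[i + 1].lower() in _LENGTH_UNITS:
            unit = standardize_unit(s.tokens[i + 1])
        qualifier = ""
        before = " ".join(s.tokens[max(0, i - 2):i]).lower()
        q = _QUALIFIER_RE.search(before + " ")
        if q:
            qualifier = q.group(1)
        out.append(standardize_value(StructuredValue(
            main_value=normalize_range_text(tok),
            modifier=qualifier,
            unit=unit,
        )))
    return out


# ---------------------------------------------------------------------------
# growth triplets (temperature / pH / NaCl)


@dataclass
class GrowthTriplet:
    """Minimum/optimum/maximum of one growth quantity in one sentence."""

    quantity: str  # "temperature" | "ph" | "nacl"
    minimum: NumericMention | None = None
    optimum: NumericMention | None = None
    maximum: NumericMention | None = None
    sub_character: str = ""


_SLOTS = ("minimum", "optimum", "maximum")

_OPT_CUE = re.compile(r"optim", re.IGNORECASE)
_MIN_CUE = re.compile(r"at least|minimum|min\.|more than|greater than|above",
                      re.IGNORECASE)
_MAX_CUE = re.compile(r"up to|maximum|max\.|below|less than", re.IGNORECASE)

_TEMP_UNIT = re.compile(r"^\s?°\s?C\b")
_NACL_UNIT = re.compile(r"^\s?(%|M\b|g l[−-]1|g/l)")
_SALT = re.compile(
    r"(sea salts|NaCl|MgSO4|MgCl2|KCl|Na2SO4|salts|salt|salinity)",
)
_PH_BEFORE = re.compile(r"pH\s?$")


def _cut_clause(before: str) -> str:
    """Context window bounded by the last clause/paren boundary."""
    idx = max(before.rfind(c) for c in ");.")
    return before[idx + 1:] if idx >= 0 else before


def _classify_quantity(text: str, start: int, end: int) -> tuple[str | None, str]:
    """Quantity of the mention at [start:end) and its unit surface form."""
    after = text[end:end + 25]
    before = text[max(0, start - 45):start]
    if _TEMP_UNIT.match(after):
        return "temperature", "°C"
    m = _NACL_UNIT.match(after)
    if m and (_SALT.search(after[:25]) or _SALT.search(before)):
        return "nacl", m.group(1)
    if _PH_BEFORE.search(before) or re.search(r"pH", before[-15:]):
        return "ph", ""
    if re.search(r"temperature", before, re.IGNORECASE):
        return "temperature", ""
    if m:  # a bare concentration with a salt word elsewhere in the clause
        clause = _cut_clause(before) + after
        if _SALT.search(clause):
            return "nacl", m.group(1)
    return None, ""


def extract_growth_mentions(
    s: AnnotatedSentence, quantity: str
) -> dict[str, list[NumericMention]]:
    """All numeric mentions of one growth quantity, keyed by triplet slot."""
    if quantity not in ("temperature", "ph", "nacl"):
        raise ValueError(f"unknown growth quantity {quantity!r}")
    text = s.text
    slots: dict[str, list[NumericMention]] = {k: [] for k in _SLOTS}
    for m in _RANGE_RE.finditer(text):
        q, unit_sf = _classify_quantity(text, m.start(), m.end())
        if q != quantity:
            continue
        low = float(m.group(1))
        high = float(m.group(2)) if m.group(2) else low
        window = _cut_clause(text[max(0, m.start() - 45):m.start()])
        surface = normalize_range_text(m.group(0))
        unit = standardize_unit(unit_sf)
        def mention(txt: str, lo: float, hi: float) -> NumericMention:
            return NumericMention(low=lo, high=hi, text=txt, unit=unit,
                                  span=(m.start(), m.end()))
        if _OPT_CUE.search(window):
            slots["optimum"].append(mention(surface, low, high))
        elif _MIN_CUE.search(window):
            slots["minimum"].append(mention(surface, low, high))
        elif _MAX_CUE.search(window):
            slots["maximum"].append(mention(surface, low, high))
        elif high > low:
            # bare range: minimum–maximum of the growth envelope
            slots["minimum"].append(mention(m.group(1), low, low))
            slots["maximum"].append(mention(m.group(2), high, high))
        # a bare point value is left unassigned: the description did not
        # say whether it is a minimum, optimum or maximum
    return slots


def extract_growth_triplet(s: AnnotatedSentence, quantity: str) -> GrowthTriplet:
    """First mention per slot, as a triplet record."""
    slots = extract_growth_mentions(s, quantity)
    for k, ms in slots.items():
        if len(ms) > 1:
            logger.warning(
                "multiple %s %s values in %r; keeping all in value lists",
                quantity, k, s.text,
            )
    sub = ""
    if quantity == "nacl":
        sm = _SALT.search(s.text)
        if sm:
            sub = sm.group(1)
            if sub in ("salts", "salt", "salinity"):
                sub = "NaCl"
        else:
            sub = "NaCl"
    t = GrowthTriplet(
        quantity=quantity,
        minimum=slots["minimum"][0] if slots["minimum"] else None,
        optimum=slots["optimum"][0] if slots["optimum"] else None,
        maximum=slots["maximum"][0] if slots["maximum"] else None,
        sub_character=sub,
    )
    return t


def _mention_to_value(m: NumericMention, quantity: str,
                      sub: str) -> StructuredValue:
    unit = m.unit
    if quantity == "ph":
        unit = ""  # pH is dimensionless; the anchor word is not a unit
    return standardize_value(StructuredValue(
        main_value=m.text,
        modifier=m.qualifier,
        unit=unit,
        sub_character=sub if quantity == "nacl" else "",
    ))


def extract_growth_values(
    s: AnnotatedSentence, character_id: str
) -> list[StructuredValue]:
    """Structured values for one triplet character (e.g. ``ph_minimum``)."""
    char = CHARACTERS_BY_ID[character_id]
    _, quantity, slot = char.extractor.split(":")
    slots = extract_growth_mentions(s, quantity)
    sub = ""
    if quantity == "nacl":
        sm = _SALT.search(s.text)
        sub = sm.group(1) if sm else "NaCl"
        if sub in ("salts", "salt", "salinity"):
            sub = "NaCl"
    return [_mention_to_value(m, quantity, sub) for m in slots[slot]]
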