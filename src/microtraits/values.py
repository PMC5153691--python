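"""Structured character values.

Both the gold standard matrix and the extractor output encode each
character state as a five-field record

    negation │ modifier │ main value │ unit │ sub-character

with ``│`` (U+2502) as the separator and the main value as the only
required field.  "not strictly anaerobic" becomes
``not │ strictly │ anaerobic``; "2–3% NaCl" becomes ``2–3 │ % │ NaCl``.
The sub-character field records the kind of salt (NaCl, sea salts,
MgSO4, …) and is only used by the salt-concentration characters.

On disk, empty fields are omitted, which makes short forms ambiguous:
``not │ motile`` is negation+main while ``plump │ rods`` is
modifier+main, and ``2–3 │ % │ NaCl`` is main+unit+sub with the leading
fields absent rather than empty.  Parsing therefore depends on the
owning character's value kind: for categorical values the last field is
the main value and leading fields are split negation-first using a small
negation-cue lexicon; for numeric values the digit-bearing field anchors
the main value, fields after it fill unit then sub-character, and fields
before it fill negation/modifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

SEPARATOR = "│"  # │

#: Cue words recognized as a pure negation field.
NEGATION_CUES = frozenset(
    {"not", "no", "non", "neither", "nor", "does not", "do not", "without"}
)

_DIGIT = re.compile(r"\d")


@dataclass(frozen=True)
class StructuredValue:
    """One character state in the five-field structured format."""

    main_value: str
    negation: str = ""
    modifier: str = ""
    unit: str = ""
    sub_character: str = ""

    def __post_init__(self) -> None:
        if not self.main_value.strip():
            raise ValueError("main_value must be non-empty")

    @property
    def fields(self) -> tuple[str, str, str, str, str]:
        """Fields in canonical order negation/modifier/main/unit/sub."""
        return (
            self.negation,
            self.modifier,
            self.main_value,
            self.unit,
            self.sub_character,
        )

    def replace(self, **kw) -> "StructuredValue":
        return replace(self, **kw)


def _clean_fields(text: str) -> list[str]:
    return [f.strip() for f in text.split(SEPARATOR)]


def parse_structured_value(text: str, value_kind: str = "categorical") -> StructuredValue:
    """Parse a ``│``-separated value string.

    ``value_kind`` ("categorical" or "numeric") selects the
    field-assignment convention of the owning character (see module
    docstring).
    """
    fields = _clean_fields(text)
    if len(fields) > 5:
        raise ValueError(f"too many fields ({len(fields)}) in {text!r}")
    if len(fields) == 1:
        return StructuredValue(main_value=fields[0])
    if value_kind == "numeric":
        return _parse_numeric_fields(fields, text)
    return _parse_categorical_fields(fields, text)


def _parse_numeric_fields(fields: list[str], text: str) -> StructuredValue:
    # The main value is the first digit-bearing field; trailing fields are
    # unit then sub-character, leading fields negation/modifier.
    main_idx = next(
        (i for i, f in enumerate(fields) if _DIGIT.search(f)), None
    )
    if main_idx is None:
        # No numeral anywhere (e.g. a verbal statement in a numeric
        # column): fall back to the categorical convention.
        return _parse_categorical_fields(fields, text)
    after = fields[main_idx + 1:]
    before = fields[:main_idx]
    if len(after) > 2 or len(before) > 2:
        raise ValueError(f"cannot assign fields of {text!r}")
    unit = after[0] if len(after) >= 1 else ""
    sub = after[1] if len(after) == 2 else ""
    negation = modifier = ""
    if len(before) == 2:
        negation, modifier = before
    elif len(before) == 1:
        if before[0].lower() in NEGATION_CUES:
            negation = before[0]
        else:
            modifier = before[0]
    return StructuredValue(
        main_value=fields[main_idx],
        negation=negation,
        modifier=modifier,
        unit=unit,
        sub_character=sub,
    )


def _parse_categorical_fields(fields: list[str], text: str) -> StructuredValue:
    if len(fields) > 3:
        raise ValueError(f"too many fields for a string value: {text!r}")
    main = fields[-1]
    negation = modifier = ""
    leading = fields[:-1]
    if len(leading) == 2:
        negation, modifier = leading
    elif len(leading) == 1:
        if leading[0].lower() in NEGATION_CUES:
            negation = leading[0]
        else:
            modifier = leading[0]
    return StructuredValue(main_value=main, negation=negation, modifier=modifier)


def serialize_structured_value(v: StructuredValue) -> str:
    """Render a value in the on-disk format, omitting empty fields."""
    parts = [f for f in v.fields if f]
    return f" {SEPARATOR} ".join(parts)
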