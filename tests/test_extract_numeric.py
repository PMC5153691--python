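"""Numeric extraction rules against their worked examples."""

import pytest
from hypothesis import given, settings, strategies as st

from microtraits.extract_numeric import (
    UNIT_SYNONYMS,
    extract_cell_dimension,
    extract_gc_content,
    extract_growth_triplet,
    extract_growth_values,
    parse_numeric_range,
    standardize_value,
)
from microtraits.values import StructuredValue, serialize_structured_value


def _ser(values):
    return [serialize_structured_value(v) for v in values]


@pytest.mark.parametrize(
    "text, low, high, qualifier, unit",
    [
        ("33.1–34.4", 33.1, 34.4, "", ""),
        ("up to 4 μm", 4.0, 4.0, "up to", "μm"),
        ("2.5", 2.5, 2.5, "", ""),
        ("6-8", 6.0, 8.0, "", ""),
        ("at least 1.7 M", 1.7, 1.7, "at least", "M"),
    ],
)
def test_parse_numeric_range(text, low, high, qualifier, unit):
    m = parse_numeric_range(text)
    assert (m.low, m.high, m.qualifier, m.unit) == (low, high, qualifier, unit)


def test_parse_numeric_range_no_match():
    assert parse_numeric_range("not determined") is None


@pytest.mark.parametrize(
    "sentence, expected",
    [
        ("DNA G + C content is 33.1–34.4 mol%.", ["33.1–34.4 │ mol%"]),
        ("The G+C content of the type strain is 55.2 mol%.", ["55.2 │ mol%"]),
        ("G+C content was not determined.", []),
    ],
)
def test_extract_gc_content(annotate, sentence, expected):
    assert _ser(extract_gc_content(annotate(sentence))) == expected


@pytest.mark.parametrize(
    "sentence, dimension, expected",
    [
        ("Cells are 0.3–0.5 μm in diameter.", "diameter", ["0.3–0.5 │ μm"]),
        ("Cells are slender rods that are 0.35–0.5 μm wide and 2.5 μm long.",
         "width", ["0.35–0.5 │ μm"]),
        ("Cells are slender rods that are 0.35–0.5 μm wide and 2.5 μm long.",
         "length", ["2.5 │ μm"]),
        # keyword precedes the numeral: lower-priority symmetric window
        ("In addition, cells have an outer diameter of 1.5–3.0 μm and width "
         "of 0.5–0.9 μm.", "width", ["0.5–0.9 │ μm"]),
        ("In addition, cells have an outer diameter of 1.5–3.0 μm and width "
         "of 0.5–0.9 μm.", "diameter", ["1.5–3.0 │ μm"]),
        ("In glucose broth, the bacilli are longer, up to 4 μm long.",
         "length", ["up to │ 4 │ μm"]),
        ("Cells are motile.", "length", []),
    ],
)
def test_extract_cell_dimension(annotate, sentence, dimension, expected):
    assert _ser(extract_cell_dimension(annotate(sentence), dimension)) == expected


def test_one_numeral_feeds_one_dimension(annotate):
    s = annotate("Cells are 2.5 μm long.")
    assert _ser(extract_cell_dimension(s, "length")) == ["2.5 │ μm"]
    assert extract_cell_dimension(s, "width") == []
    assert extract_cell_dimension(s, "diameter") == []


TABLE_SENTENCE = (
    "Growth occurs at temperatures in the range 38–68 °C (optimum, 60 °C) "
    "and at pH 1.8–4.0 (optimum, pH 3.0)."
)


@pytest.mark.parametrize(
    "character_id, expected",
    [
        ("temperature_minimum", ["38 │ °C"]),
        ("temperature_optimum", ["60 │ °C"]),
        ("temperature_maximum", ["68 │ °C"]),
        ("ph_minimum", ["1.8"]),
        ("ph_optimum", ["3.0"]),
        ("ph_maximum", ["4.0"]),
    ],
)
def test_growth_triplet_range_optimum(annotate, character_id, expected):
    assert _ser(extract_growth_values(annotate(TABLE_SENTENCE),
                                      character_id)) == expected


def test_growth_triplet_at_least_optimally(annotate):
    s = annotate("Growth requires at least 1.7 M NaCl, optimally 3.0–4.3 M NaCl.")
    assert _ser(extract_growth_values(s, "nacl_minimum")) == ["1.7 │ M │ NaCl"]
    assert _ser(extract_growth_values(s, "nacl_optimum")) == ["3.0–4.3 │ M │ NaCl"]
    assert extract_growth_values(s, "nacl_maximum") == []


def test_growth_bare_range(annotate):
    s = annotate("Grows at pH 6–8.")
    assert _ser(extract_growth_values(s, "ph_minimum")) == ["6"]
    assert _ser(extract_growth_values(s, "ph_maximum")) == ["8"]
    assert extract_growth_values(s, "ph_optimum") == []


def test_bare_point_value_never_promoted_to_optimum(annotate):
    # "stay true to the description": a growth observation is not an optimum
    s = annotate("Good growth occurs on MA at 1–25 °C.")
    assert extract_growth_values(s, "temperature_optimum") == []


def test_growth_triplet_record(annotate):
    t = extract_growth_triplet(annotate(TABLE_SENTENCE), "temperature")
    assert (t.minimum.low, t.optimum.low, t.maximum.high) == (38.0, 60.0, 68.0)
    assert t.minimum.low <= t.maximum.high


def test_standardize_micron_spelling():
    v = StructuredValue("1.2-2.4", unit="microns")
    assert serialize_structured_value(standardize_value(v)) == "1.2–2.4 │ μm"


def test_standardize_fixed_point():
    v = StructuredValue("60", unit="°C")
    assert standardize_value(v) == v


@settings(max_examples=200, derandomize=True)
@given(
    st.sampled_from([s for syns in UNIT_SYNONYMS.values() for s in syns]),
    st.integers(1, 99),
)
def test_standardize_idempotent_over_synonym_table(unit, n):
    v = StructuredValue(f"{n}-{n + 2}", unit=unit)
    once = standardize_value(v)
    assert standardize_value(once) == once


def test_extracted_values_reparse(annotate, small_corpus, term_lists):
    """Every numeric value emitted on the fixture corpus re-parses with
    low <= high."""
    from microtraits.characters import CHARACTERS
    from microtraits.pipeline import ExtractionPipeline
    from microtraits.preprocess import annotate_description

    descs, _, _ = small_corpus
    pipe = ExtractionPipeline(term_lists=term_lists, bank=None)
    numeric = {c.id for c in CHARACTERS if c.value_kind == "numeric"}
    seen = 0
    for d in descs[:4]:
        for s in annotate_description(d.paragraphs, d.taxon_name):
            for cid, values in pipe.extract_sentence(s).items():
                if cid not in numeric:
                    continue
                for v in values:
                    m = parse_numeric_range(v.main_value)
                    assert m is not None and m.low <= m.high
                    seen += 1
    assert seen > 20
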