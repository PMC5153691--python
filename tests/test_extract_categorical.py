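"""Term matching, coordination, dependency patterns, polarity routing."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from microtraits.characters import get_character
from microtraits.corpus_io import TermList
from microtraits.extract_categorical import (
    DEFAULT_PATTERNS,
    NounPhrase,
    apply_dependency_pattern,
    chunk_noun_phrases,
    expand_coordination,
    extract_categorical,
    term_match,
)
from microtraits.values import StructuredValue


def _pattern(name):
    return next(p for p in DEFAULT_PATTERNS if p.name == name)


def _mains(values):
    return [v.main_value for v in values]


class TestChunking:
    def test_coordinated_phrases_share_a_group(self, annotate):
        s = annotate("Chloramphenicol, streptomycin and kanamycin are effective.")
        ps = chunk_noun_phrases(s)
        assert [p.text for p in ps[:3]] == [
            "Chloramphenicol", "streptomycin", "kanamycin"
        ]
        assert len({p.coordination_group for p in ps[:3]}) == 1
        assert ps[0].coordination_group is not None

    def test_predicate_adjective_is_not_a_noun_phrase(self, annotate):
        ps = chunk_noun_phrases(annotate("Cells are motile."))
        assert [p.text for p in ps] == ["Cells"]

    def test_premodified_noun_phrase(self, annotate):
        ps = chunk_noun_phrases(annotate("Some cells are arranged in short chains."))
        assert "short chains" in [p.text for p in ps]

    def test_phrases_in_group_do_not_overlap(self, annotate):
        s = annotate("Requires glucose, fructose, sucrose and maltose.")
        ps = chunk_noun_phrases(s)
        grouped = [p for p in ps if p.coordination_group is not None]
        for a, b in itertools.combinations(grouped, 2):
            assert a.span[1] <= b.span[0] or b.span[1] <= a.span[0]


class TestTermMatch:
    def test_full_phrase_extracted_not_bare_term(self, annotate):
        ps = chunk_noun_phrases(annotate("Some cells are arranged in short chains."))
        tl = TermList.from_terms("cell_aggregation", ["chains"])
        (match,) = [term_match(p, tl) for p in ps if term_match(p, tl)]
        assert match.main_value == "short chains"

    def test_full_phrase_keeps_premodifier_brown(self, annotate):
        ps = chunk_noun_phrases(annotate("They form slightly brown colonies."))
        tl = TermList.from_terms("colony_color", ["brown"])
        matches = [term_match(p, tl) for p in ps if term_match(p, tl)]
        assert any(m.main_value == "slightly brown colonies" for m in matches)

    def test_empty_list_matches_nothing(self, annotate):
        ps = chunk_noun_phrases(annotate("Ferments mannitol."))
        tl = TermList.from_terms("organic_used", [])
        assert all(term_match(p, tl) is None for p in ps)

    def test_match_is_whole_word(self):
        p = NounPhrase("mannitol", 0, (0, 1))
        tl = TermList.from_terms("organic_used", ["man"])
        assert term_match(p, tl) is None

    def test_output_contains_a_list_term(self, annotate, term_lists):
        ps = chunk_noun_phrases(annotate("Some cells are arranged in loose clusters."))
        tl = term_lists["cell_aggregation"]
        for p in ps:
            m = term_match(p, tl)
            if m:
                assert any(t in m.main_value.lower() for t in tl.terms)


class TestCoordinationExpansion:
    def test_one_match_pulls_in_whole_group(self, annotate):
        s = annotate("Chloramphenicol, streptomycin and kanamycin are effective.")
        ps = chunk_noun_phrases(s)
        matched = [p for p in ps if p.text == "streptomycin"]
        got = expand_coordination(ps, matched)
        assert {v.main_value for v in got} >= {
            "Chloramphenicol", "streptomycin", "kanamycin"
        }

    def test_no_match_no_expansion(self, annotate):
        ps = chunk_noun_phrases(annotate("Glucose, fructose and sucrose."))
        assert expand_coordination(ps, []) == set()

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 4), st.booleans()),
                    min_size=1, max_size=8, unique_by=lambda t: t))
    def test_matches_brute_force_set_expansion(self, spec):
        # phrases with synthetic group ids; oracle: matched ∪ hit groups
        phrases = [
            NounPhrase(f"p{i}", i, (i, i + 1),
                       coordination_group=g if g < 3 else None)
            for i, (g, _) in enumerate(spec)
        ]
        matched = [p for p, (_, m) in zip(phrases, spec) if m]
        got = {v.main_value for v in expand_coordination(phrases, matched)}
        hit = {p.coordination_group for p in matched
               if p.coordination_group is not None}
        oracle = {p.text for p in phrases
                  if p in matched or p.coordination_group in hit}
        assert got == oracle
        # idempotent/monotone: expanding the expansion changes nothing
        expanded = [p for p in phrases if p.text in got]
        again = {v.main_value for v in expand_coordination(phrases, expanded)}
        assert again == got


class TestDependencyPatterns:
    def test_produced_from_roles(self, annotate):
        s = annotate("Acid is produced from glucose and fructose.")
        got = apply_dependency_pattern(s, _pattern("produced-from"))
        assert _mains(e.value for e in got["fermentation_products"]) == ["Acid"]
        assert _mains(e.value for e in got["fermentation_substrates_used"]) == [
            "glucose", "fructose"
        ]

    def test_bare_passive_goes_to_other_products(self, annotate):
        s = annotate("Acetoin is produced.")
        got = apply_dependency_pattern(s, _pattern("produced-bare"))
        assert _mains(e.value for e in got["other_metabolic_products"]) == ["Acetoin"]
        # and the from-pattern stays silent without its particle
        assert apply_dependency_pattern(s, _pattern("produced-from")) == {}

    def test_negated_trigger_routes_to_partner(self, annotate):
        s = annotate("And no acid is produced from glycerol, erythritol and ribose.")
        got = apply_dependency_pattern(s, _pattern("produced-from"))
        assert _mains(e.value for e in got["fermentation_substrates_not_used"]) == [
            "glycerol", "erythritol", "ribose"
        ]
        assert "fermentation_products" not in got

    def test_term_matched_filler_is_high_confidence(self, annotate):
        s = annotate("Acid is produced from glucose.")
        tls = {"fermentation_substrates_used":
               TermList.from_terms("fermentation_substrates_used", ["glucose"])}
        got = apply_dependency_pattern(s, _pattern("produced-from"), tls)
        (e,) = got["fermentation_substrates_used"]
        assert e.high_confidence

    def test_trigger_absent_empty_map(self, annotate):
        s = annotate("Cells are motile.")
        assert apply_dependency_pattern(s, _pattern("produced-from")) == {}


class TestPolarityRouting:
    def test_but_not_list_splits_used_and_not_used(self, annotate, term_lists):
        s = annotate(
            "Arabinose, mannose and maltose are used as carbon sources, "
            "but not mannitol, gluconate and malate."
        )
        got = extract_categorical(s, get_character("organic_used"), term_lists)
        assert _mains(got["organic_used"]) == ["Arabinose", "mannose", "maltose"]
        assert _mains(got["organic_not_used"]) == [
            "mannitol", "gluconate", "malate"
        ]

    def test_used_and_not_used_are_disjoint(self, annotate, term_lists):
        s = annotate(
            "Citrate and esculin are used as carbon sources, but not adipate."
        )
        got = extract_categorical(s, get_character("organic_used"), term_lists)
        used = {v.main_value.lower() for v in got.get("organic_used", [])}
        not_used = {v.main_value.lower() for v in got.get("organic_not_used", [])}
        assert used and not_used and not (used & not_used)

    def test_no_determiner_phrase_kept_verbatim(self, annotate, term_lists):
        s = annotate("No spores are observed.")
        got = extract_categorical(s, get_character("internal_features"),
                                  term_lists)
        assert _mains(got["internal_features"]) == ["No spores"]

    def test_non_motile_kept_verbatim(self, annotate, term_lists):
        s = annotate("Cells are non-motile, extremely pleomorphic.")
        got = extract_categorical(s, get_character("motility"), term_lists)
        assert _mains(got["motility"]) == ["non-motile"]

    def test_not_motile_fills_negation_field(self, annotate, term_lists):
        s = annotate("Cells are not motile.")
        got = extract_categorical(s, get_character("motility"), term_lists)
        (v,) = got["motility"]
        assert (v.negation, v.main_value) == ("not", "motile")
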