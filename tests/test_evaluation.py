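"""Rigid/relaxed hit scoring, alignment, and report arithmetic."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from microtraits.evaluation import (
    align_and_score,
    compute_report,
    score_value_pair,
)
from microtraits.matrix_builder import build_matrix
from microtraits.values import StructuredValue as SV, parse_structured_value


def P(text, kind="categorical"):
    return parse_structured_value(text, kind)


WORKED_PAIRS = [
    # (extracted, gsm, kind, rigid, relaxed)
    ("55.2 │ mol%", "55.2 │ mol%", "numeric", 1, 1),
    ("Neither lactate nor pyruvate", "esculin", "categorical", 0, 0),
    ("plump │ rods", "short plump │ rods", "categorical", 0.5, 1),
    ("not │ motile", "not │ motile by gliding", "categorical", 0.5, 0.5),
    ("Most strains ferment arbutin", "arbutin", "categorical", 0.5, 1),
]


@pytest.mark.parametrize("ext, gsm, kind, rigid, relaxed", WORKED_PAIRS)
def test_pair_scores(ext, gsm, kind, rigid, relaxed):
    s = score_value_pair(P(ext, kind), P(gsm, kind), kind)
    assert (s.rigid, s.relaxed) == (rigid, relaxed)


def test_negation_polarity_mismatch_scores_zero():
    assert score_value_pair(P("motile"), P("not │ motile")).relaxed == 0
    assert score_value_pair(P("not │ motile"), P("motile")).relaxed == 0


def test_unit_mismatch_alone_is_rule_three():
    s = score_value_pair(P("1.2–2.4 │ microns", "numeric"),
                         P("1.2–2.4 │ μm", "numeric"), "numeric")
    assert (s.rigid, s.relaxed) == (1, 1)  # synonymous units standardize away
    s = score_value_pair(P("2.4 │ mm", "numeric"),
                         P("2.4 │ μm", "numeric"), "numeric")
    assert (s.rigid, s.relaxed) == (0.5, 1)


def test_hyphen_and_en_dash_ranges_compare_equal():
    s = score_value_pair(P("6-8", "numeric"), P("6–8", "numeric"), "numeric")
    assert (s.rigid, s.relaxed) == (1, 1)


def test_asymmetry_of_containment_rules():
    # extra surrounding tokens in the extraction are forgiven (relaxed=1);
    # a truncated extraction is only half right either way
    wide = score_value_pair(P("Most strains ferment arbutin"), P("arbutin"))
    narrow = score_value_pair(P("arbutin"), P("Most strains ferment arbutin"))
    assert (wide.rigid, wide.relaxed) == (0.5, 1)
    assert (narrow.rigid, narrow.relaxed) == (0.5, 0.5)


def test_cell_alignment_example_three():
    cell = align_and_score([P("plump │ rods"), P("short")],
                           [P("short plump │ rods")])
    assert (cell.hit_sum_rigid, cell.hit_sum_relaxed) == (0.5, 1)
    assert (cell.n_extracted, cell.n_gsm) == (2, 1)


def test_cell_alignment_example_five():
    gsm = [P(x) for x in ["arbutin", "salicin", "D-raffinose", "D-mannose",
                          "sucrose", "melibiose"]]
    ext = [P(x) for x in ["melibiose", "sucrose", "D-mannose", "D-raffinose",
                          "salicin", "Most strains ferment arbutin"]]
    cell = align_and_score(ext, gsm)
    assert (cell.hit_sum_rigid, cell.hit_sum_relaxed) == (5.5, 6)


def test_empty_cells():
    cell = align_and_score([], [])
    assert (cell.hit_sum_rigid, cell.n_extracted, cell.n_gsm) == (0, 0, 0)
    cell = align_and_score([P("motile")], [])
    assert (cell.hit_sum_relaxed, cell.n_extracted) == (0, 1)


def _table2_matrices():
    rows = [
        ("Ex1", "gc_content", ["55.2 │ mol%"], ["55.2 │ mol%"], "numeric"),
        ("Ex2", "organic_not_used", ["Neither lactate nor pyruvate"],
         ["esculin"], "categorical"),
        ("Ex3", "cell_shape", ["plump │ rods", "short"],
         ["short plump │ rods"], "categorical"),
        ("Ex4", "motility", ["not │ motile"], ["not │ motile by gliding"],
         "categorical"),
        ("Ex5", "fermentation_substrates_used",
         ["melibiose", "sucrose", "D-mannose", "D-raffinose", "salicin",
          "Most strains ferment arbutin"],
         ["arbutin", "salicin", "D-raffinose", "D-mannose", "sucrose",
          "melibiose"], "categorical"),
    ]
    out = build_matrix(
        (t, c, P(v, k)) for t, c, ext, _, k in rows for v in ext
    )
    gsm = build_matrix(
        (t, c, P(v, k)) for t, c, _, gold, k in rows for v in gold
    )
    return out, gsm


def test_report_totals_and_metric_formulas():
    out, gsm = _table2_matrices()
    report = compute_report(out, gsm)
    t = report.totals
    assert (t.rigid_sum, t.relaxed_sum) == (7.5, 8.5)
    assert (t.n_extracted, t.n_gsm) == (11, 10)
    p, r, f1 = t.rigid_prf
    assert p == pytest.approx(7.5 / 11, abs=5e-4)
    assert r == pytest.approx(7.5 / 10, abs=5e-4)
    assert f1 == pytest.approx(2 * p * r / (p + r), abs=5e-4)


def test_self_evaluation_identity(small_corpus):
    _, gsm, _ = small_corpus
    report = compute_report(gsm, gsm)
    for cs in report.per_character.values():
        if cs.n_gsm:
            assert cs.rigid_prf == (1.0, 1.0, 1.0)
            assert cs.relaxed_prf == (1.0, 1.0, 1.0)
    assert report.overall_accuracy == 1.0


def test_taxon_mismatch_raises():
    out, gsm = _table2_matrices()
    out.taxa.append("Phantom taxon")
    with pytest.raises(ValueError, match="Phantom taxon"):
        compute_report(out, gsm)


_small_value = st.sampled_from([
    SV("motile"), SV("motile", negation="not"), SV("rods"),
    SV("rods", modifier="short"), SV("short plump rods"), SV("arbutin"),
    SV("ferments arbutin"), SV("55.2", unit="mol%"), SV("brown colonies"),
])


@settings(max_examples=500, derandomize=True, deadline=None)
@given(st.lists(_small_value, max_size=4), st.lists(_small_value, max_size=4))
def test_alignment_matches_exhaustive_search(ext, gsm):
    """The optimal-assignment scorer equals brute force over all
    one-to-one assignments, and relaxed >= rigid throughout."""
    cell = align_and_score(ext, gsm)
    assert cell.hit_sum_relaxed >= cell.hit_sum_rigid
    best_relaxed = 0.0
    k = min(len(ext), len(gsm))
    for idx_e in itertools.permutations(range(len(ext)), k):
        for idx_g in itertools.permutations(range(len(gsm)), k):
            total = sum(
                score_value_pair(ext[i], gsm[j]).relaxed
                for i, j in zip(idx_e, idx_g)
            )
            best_relaxed = max(best_relaxed, total)
    assert cell.hit_sum_relaxed == pytest.approx(best_relaxed)


@settings(max_examples=300, derandomize=True)
@given(_small_value, _small_value)
def test_relaxed_never_below_rigid(a, b):
    s = score_value_pair(a, b)
    assert s.relaxed >= s.rigid
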