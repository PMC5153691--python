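"""Synthetic taxonomic descriptions with exact ground truth.

No description corpus is shipped with the package, so every pipeline
stage — classifier training, extraction, end-to-end evaluation — is
exercised on generated descriptions.  Each sentence template mirrors a
construction that real prokaryotic descriptions use for one or more
characters ("DNA G + C content is … mol%.", "Growth occurs at
temperatures in the range A–B °C (optimum, C °C).", "… but not X, Y and
Z."), with typed slots drawn from small per-character vocabularies.  The
truth rule of a template yields exactly the structured values an
extractor must recover, so a generated corpus comes with a perfect gold
standard matrix and labeled training instances.

Templates intentionally include the hard constructions: "(optimum, …)"
parentheticals, "at least … optimally …" phrasing, "but not"
coordination lists, negated determiner phrases ("No spores"), verbatim
negative adjectives ("non-motile"), and a term ("filamentous") shared by
the Cell Shape and Colony Shape vocabularies so that the effect of
sentence triage on precision can be measured.  Distractor (noise)
sentences carry no target values and use a disjoint vocabulary.

The fixtures validate mechanism, not corpus-level performance: they do
not mimic the lexical richness, typography or ambiguity of real
journal prose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .characters import CHARACTER_IDS
from .corpus_io import TaxonDescription, TermList, TrainingInstance
from .matrix_builder import TaxonCharacterMatrix
from .values import StructuredValue

Rng = np.random.Generator
Truth = dict[str, list[StructuredValue]]


@dataclass(frozen=True)
class TemplateSpec:
    """A sentence template plus the rule giving its ground-truth values."""

    name: str
    characters: tuple[str, ...]
    render: Callable[[Rng], tuple[str, Truth]]
    vocabulary: dict[str, tuple[str, ...]]


def _sv(main: str, **kw) -> StructuredValue:
    return StructuredValue(main_value=main, **kw)


def _r1(rng: Rng, lo: float, hi: float) -> float:
    return round(float(rng.uniform(lo, hi)), 1)


def _pick(rng: Rng, options: Sequence[str]) -> str:
    return str(options[int(rng.integers(len(options)))])


def _picks(rng: Rng, options: Sequence[str], n: int) -> list[str]:
    idx = rng.choice(len(options), size=n, replace=False)
    return [str(options[int(i)]) for i in idx]


# ------------------------------------------------------------------ vocabularies

VOCAB: dict[str, tuple[str, ...]] = {
    "gram": ("Gram-negative", "Gram-positive", "Gram-variable"),
    "motility": ("motile", "non-motile"),
    "aero_adv": ("Strictly", "Obligately", "Facultatively"),
    "aero_state": ("anaerobic", "aerobic"),
    "agg_mod": ("short", "long", "loose"),
    "agg": ("chains", "pairs", "clusters", "filaments"),
    "internal": ("spores", "endospores", "granules"),
    "color": ("red", "yellow", "orange", "pink", "brown"),
    "antibiotic": ("tetracycline", "rifampicin", "vancomycin", "streptomycin",
                   "chloramphenicol", "kanamycin", "ampicillin",
                   "erythromycin", "gentamicin"),
    "product": ("Acid", "Gas"),
    "sugar": ("glucose", "fructose", "sucrose", "lactose", "melibiose",
              "salicin"),
    "compound": ("arabinose", "mannose", "maltose", "mannitol", "gluconate",
                 "caprate", "adipate", "citrate", "malate", "esculin"),
    "cell_shape": ("rod-shaped", "coccoid", "filamentous", "spiral-shaped"),
    "colony_shape": ("circular", "convex", "punctiform", "rhizoid"),
    "vitamin": ("Vitamin K1", "haemin", "biotin", "thiamine"),
    "salinity": ("sea salts",),
    "place": ("a hot spring", "marine sediment", "forest soil", "a soda lake"),
    "epithet": ("type locality", "isolation source"),
}


def _vocab(*keys: str) -> dict[str, tuple[str, ...]]:
    return {k: VOCAB[k] for k in keys}


# ------------------------------------------------------------------ templates


def _render_gc(rng: Rng):
    lo = _r1(rng, 30, 70)
    hi = round(lo + _r1(rng, 0.5, 5), 1)
    r = f"{lo}–{hi}"
    return (f"DNA G + C content is {r} mol%.",
            {"gc_content": [_sv(r, unit="mol%")]})


def _render_dimension(which: str, phrase: str):
    def render(rng: Rng):
        lo = _r1(rng, 0.2, 3)
        hi = round(lo + _r1(rng, 0.1, 2), 1)
        r = f"{lo}–{hi}"
        return (f"Cells are {r} μm {phrase}.",
                {which: [_sv(r, unit="μm")]})
    return render


def _render_temperature(rng: Rng):
    a = int(rng.integers(4, 30))
    b = a + int(rng.integers(10, 40))
    c = (a + b) // 2
    return (
        f"Growth occurs at temperatures in the range {a}–{b} °C "
        f"(optimum, {c} °C).",
        {
            "temperature_minimum": [_sv(str(a), unit="°C")],
            "temperature_optimum": [_sv(str(c), unit="°C")],
            "temperature_maximum": [_sv(str(b), unit="°C")],
        },
    )


def _render_ph(rng: Rng):
    a = _r1(rng, 4, 7)
    b = round(a + _r1(rng, 1, 3), 1)
    c = round((a + b) / 2, 1)
    return (
        f"Growth occurs at pH {a}–{b} (optimum, pH {c}).",
        {
            "ph_minimum": [_sv(str(a))],
            "ph_optimum": [_sv(str(c))],
            "ph_maximum": [_sv(str(b))],
        },
    )


def _render_nacl(rng: Rng):
    a = _r1(rng, 0.5, 2)
    b = round(a + _r1(rng, 0.5, 2), 1)
    c = round(b + _r1(rng, 0.5, 2), 1)
    return (
        f"Growth requires at least {a} M NaCl, optimally {b}–{c} M NaCl.",
        {
            "nacl_minimum": [_sv(str(a), unit="M", sub_character="NaCl")],
            "nacl_optimum": [_sv(f"{b}–{c}", unit="M", sub_character="NaCl")],
        },
    )


def _render_gram(rng: Rng):
    g = _pick(rng, VOCAB["gram"])
    return f"Cells are {g}.", {"gram_stain": [_sv(g)]}


def _render_motility(rng: Rng):
    m = _pick(rng, VOCAB["motility"])
    return f"Cells are {m} and pleomorphic.", {"motility": [_sv(m)]}


def _render_aerophilicity(rng: Rng):
    adv = _pick(rng, VOCAB["aero_adv"])
    state = _pick(rng, VOCAB["aero_state"])
    return (f"{adv} {state}.",
            {"aerophilicity": [_sv(state, modifier=adv.lower())]})


def _render_aggregation(rng: Rng):
    mod = _pick(rng, VOCAB["agg_mod"])
    agg = _pick(rng, VOCAB["agg"])
    return (f"Some cells are arranged in {mod} {agg}.",
            {"cell_aggregation": [_sv(f"{mod} {agg}")]})


def _render_internal(rng: Rng):
    feat = _pick(rng, VOCAB["internal"])
    return f"No {feat} are observed.", {"internal_features": [_sv(f"No {feat}")]}


def _render_pigment(rng: Rng):
    color = _pick(rng, VOCAB["color"])
    return (f"Pigmented {color} due to carotenoids.",
            {"pigment_compounds": [_sv(color)]})


def _render_sensitivity(rng: Rng):
    t = _picks(rng, VOCAB["antibiotic"], 3)
    return (f"Sensitive to {t[0]}, {t[1]} and {t[2]}.",
            {"antibiotic_sensitivity": [_sv(x) for x in t]})


def _render_resistance(rng: Rng):
    t = _pick(rng, VOCAB["antibiotic"])
    return (f"The type strain is resistant to {t}.",
            {"antibiotic_resistant": [_sv(t)]})


def _render_fermentation(rng: Rng):
    p = _pick(rng, VOCAB["product"])
    s = _picks(rng, VOCAB["sugar"], 2)
    return (
        f"{p} is produced from {s[0]} and {s[1]}.",
        {
            "fermentation_products": [_sv(p)],
            "fermentation_substrates_used": [_sv(x) for x in s],
        },
    )


def _render_organic(rng: Rng):
    c = _picks(rng, VOCAB["compound"], 6)
    used, not_used = c[:3], c[3:]
    # capitalize the sentence-initial compound, as descriptions do
    surface = [used[0].capitalize(), used[1], used[2]]
    return (
        f"{surface[0]}, {surface[1]} and {surface[2]} are used as carbon "
        f"sources, but not {not_used[0]}, {not_used[1]} and {not_used[2]}.",
        {
            "organic_used": [_sv(x) for x in surface],
            "organic_not_used": [_sv(x) for x in not_used],
        },
    )


def _render_cell_shape(rng: Rng):
    cs = _pick(rng, VOCAB["cell_shape"])
    return f"Cells are {cs}.", {"cell_shape": [_sv(cs)]}


def _render_colony_shape(rng: Rng):
    co = _pick(rng, VOCAB["colony_shape"])
    return (f"Colonies are {co} with entire margins.",
            {"colony_shape": [_sv(co)]})


def _render_vitamins(rng: Rng):
    v = _picks(rng, VOCAB["vitamin"], 2)
    first = v[0][0].upper() + v[0][1:]  # sentence-initial capitalization
    return (f"{first} and {v[1]} are required for growth.",
            {"vitamins_cofactors": [_sv(first), _sv(v[1])]})


def _render_salinity(rng: Rng):
    return ("Requires sea salts for growth.",
            {"salinity_requirement": [_sv("sea salts")]})


TEMPLATES: tuple[TemplateSpec, ...] = (
    TemplateSpec("gc", ("gc_content",), _render_gc, {}),
    TemplateSpec("diameter", ("cell_diameter",),
                 _render_dimension("cell_diameter", "in diameter"), {}),
    TemplateSpec("length", ("cell_length",),
                 _render_dimension("cell_length", "long"), {}),
    TemplateSpec("width", ("cell_width",),
                 _render_dimension("cell_width", "wide"), {}),
    TemplateSpec("temperature",
                 ("temperature_minimum", "temperature_optimum",
                  "temperature_maximum"), _render_temperature, {}),
    TemplateSpec("ph", ("ph_minimum", "ph_optimum", "ph_maximum"),
                 _render_ph, {}),
    TemplateSpec("nacl", ("nacl_minimum", "nacl_optimum"), _render_nacl, {}),
    TemplateSpec("gram", ("gram_stain",), _render_gram, _vocab("gram")),
    TemplateSpec("motility", ("motility",), _render_motility,
                 _vocab("motility")),
    TemplateSpec("aerophilicity", ("aerophilicity",), _render_aerophilicity,
                 _vocab("aero_state")),
    TemplateSpec("aggregation", ("cell_aggregation",), _render_aggregation,
                 _vocab("agg")),
    TemplateSpec("internal", ("internal_features",), _render_internal,
                 _vocab("internal")),
    TemplateSpec("pigment", ("pigment_compounds",), _render_pigment,
                 _vocab("color")),
    TemplateSpec("sensitivity", ("antibiotic_sensitivity",),
                 _render_sensitivity, _vocab("antibiotic")),
    TemplateSpec("resistance", ("antibiotic_resistant",), _render_resistance,
                 _vocab("antibiotic")),
    TemplateSpec("fermentation",
                 ("fermentation_products", "fermentation_substrates_used"),
                 _render_fermentation, _vocab("product", "sugar")),
    TemplateSpec("organic", ("organic_used", "organic_not_used"),
                 _render_organic, _vocab("compound")),
    TemplateSpec("cell_shape", ("cell_shape",), _render_cell_shape,
                 _vocab("cell_shape")),
    TemplateSpec("colony_shape", ("colony_shape",), _render_colony_shape,
                 _vocab("colony_shape")),
    TemplateSpec("vitamins", ("vitamins_cofactors",), _render_vitamins,
                 _vocab("vitamin")),
    TemplateSpec("salinity", ("salinity_requirement",), _render_salinity,
                 _vocab("salinity")),
)

TEMPLATE_CHARACTERS: tuple[str, ...] = tuple(
    cid for t in TEMPLATES for cid in t.characters
)

_DISTRACTORS = (
    "The type strain was isolated from {place}.",
    "The species epithet refers to the {epithet}.",
    "Phylogenetic analysis places the strain among its closest relatives.",
    "Stock cultures are maintained under standard conditions.",
)


def _select_templates(chars: Sequence[str] | None) -> list[TemplateSpec]:
    if chars is None:
        return list(TEMPLATES)
    wanted = set(chars)
    unknown = wanted - set(CHARACTER_IDS)
    if unknown:
        raise ValueError(f"unknown characters: {sorted(unknown)}")
    unsupported = wanted - set(TEMPLATE_CHARACTERS)
    if unsupported:
        raise ValueError(f"no templates for characters: {sorted(unsupported)}")
    # template closure: one sentence can carry several characters, so the
    # whole template (and its full truth) comes along
    return [t for t in TEMPLATES if wanted & set(t.characters)]


def generate_corpus(
    n_taxa: int,
    chars: Sequence[str] | None = None,
    seed: int = 0,
    noise: float = 0.0,
) -> tuple[list[TaxonDescription], TaxonCharacterMatrix, list[TrainingInstance]]:
    """Generate descriptions, their gold standard matrix, and labeled
    training instances.  Deterministic given ``seed``."""
    if not 0 <= noise <= 1:
        raise ValueError("noise must be within [0, 1]")
    templates = _select_templates(chars)
    descriptions: list[TaxonDescription] = []
    matrix = TaxonCharacterMatrix()
    instances: list[TrainingInstance] = []
    for i in range(n_taxa):
        taxon = f"Fixturella synthetica {i + 1:03d}"
        rng = np.random.default_rng([seed % (2**31), i])
        sentences: list[str] = []
        for t in templates:
            sentence, truth = t.render(rng)
            sentences.append(sentence)
            for cid in t.characters:
                for v in truth.get(cid, []):
                    matrix.add(taxon, cid, v)
                if truth.get(cid):
                    instances.append(TrainingInstance(sentence, cid))
        n_noise = int(round(noise * len(sentences)))
        for _ in range(n_noise):
            tmpl = _pick(rng, _DISTRACTORS)
            sentences.append(tmpl.format(
                place=_pick(rng, VOCAB["place"]),
                epithet=_pick(rng, VOCAB["epithet"]),
            ))
        order = rng.permutation(len(sentences))
        text = " ".join(sentences[int(j)] for j in order)
        descriptions.append(TaxonDescription(taxon_name=taxon,
                                             paragraphs=[text]))
        if taxon not in matrix.taxa:
            matrix.taxa.append(taxon)
    return descriptions, matrix, instances


_TERM_LIST_VOCAB: dict[str, tuple[str, ...]] = {
    "gram_stain": VOCAB["gram"],
    "motility": VOCAB["motility"] + ("gliding",),
    "aerophilicity": VOCAB["aero_state"] + ("microaerophilic",),
    "cell_aggregation": VOCAB["agg"],
    "internal_features": VOCAB["internal"],
    "pigment_compounds": VOCAB["color"],
    "antibiotic_sensitivity": VOCAB["antibiotic"],
    "antibiotic_resistant": VOCAB["antibiotic"],
    "fermentation_products": VOCAB["product"],
    "fermentation_substrates_used": VOCAB["sugar"],
    "fermentation_substrates_not_used": VOCAB["sugar"],
    "organic_used": VOCAB["compound"],
    "organic_not_used": VOCAB["compound"],
    "cell_shape": VOCAB["cell_shape"],
    "colony_shape": VOCAB["colony_shape"],
    "vitamins_cofactors": VOCAB["vitamin"],
    "salinity_requirement": VOCAB["salinity"],
}


def generate_term_lists(
    chars: Sequence[str] | None = None,
    seed: int = 0,
    decoy_fraction: float = 0.0,
    shared_terms: bool = False,
) -> dict[str, TermList]:
    """Fixture term lists: the full template vocabulary per character,
    plus optionally a fraction of decoy terms never used in text.

    ``shared_terms`` plants "filamentous" in the Colony Shape list as
    well as the Cell Shape list, recreating the ambiguity that makes
    sentence triage matter: without triage, the Colony Shape extractor
    fires on cell-shape sentences mentioning filaments.
    """
    rng = np.random.default_rng(seed % (2**31))
    wanted = set(chars) if chars is not None else set(_TERM_LIST_VOCAB)
    out: dict[str, TermList] = {}
    for cid, vocab in _TERM_LIST_VOCAB.items():
        if cid not in wanted:
            continue
        terms = list(vocab)
        if shared_terms and cid == "colony_shape":
            terms.append("filamentous")
        n_decoys = int(round(decoy_fraction * len(terms)))
        for _ in range(n_decoys):
            terms.append(f"decoyterm{int(rng.integers(10_000))}")
        out[cid] = TermList.from_terms(cid, terms, source="imported")
    return out
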