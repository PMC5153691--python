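"""The closed schema of 42 phenotypic characters targeted by the pipeline.

Prokaryotic taxonomic descriptions concentrate on physiology and ecology
rather than gross morphology, so the extraction targets span eight
high-level trait categories: genomic G+C content, cell morphology, growth
conditions, antibiotic physiology, colony morphology, metabolic end
products, microbe-host interactions, and metabolic substrates.

Each :class:`CharacterDef` binds a character to the extraction strategy
that suits its typical textual expression:

* ``numeric`` characters (mol% G+C, cell dimensions in μm, and the
  minimum/optimum/maximum triplets for temperature, pH and salt
  concentration) are handled by regular-expression and POS-window rules;
* ``categorical`` characters are handled by term matching — either inside
  noun phrases (``phrase`` mode, which keeps pre-modifiers such as
  "short" in "short chains") or directly against the sentence
  (``sentence`` mode, for adjective-valued states like "motile" or
  "Gram-negative") — optionally combined with dependency patterns.

Polarity partners pair a "used" character with its "not used" twin so
that negated mentions can be routed to the right column.
"""

from __future__ import annotations

from dataclasses import dataclass, field


CATEGORIES: tuple[str, ...] = (
    "G + C Content",
    "Cell Morphology",
    "Growth Condition",
    "Antibiotic Physiology",
    "Colony Morphology",
    "Metabolic End Products and Secondary Metabolites",
    "Microbe-Host Interaction",
    "Metabolic Substrate",
)


@dataclass(frozen=True)
class CharacterDef:
    """Definition of one phenotypic character (one matrix column)."""

    id: str
    display_name: str
    category: str
    value_kind: str  # "numeric" | "categorical"
    extractor: str  # binding name understood by the pipeline dispatcher
    unit_family: tuple[str, ...] = ()
    polarity_partner: str | None = None
    match_mode: str | None = None  # "phrase" | "sentence" (categorical only)
    admits_negation: bool = False

    def __post_init__(self) -> None:
        if self.value_kind not in ("numeric", "categorical"):
            raise ValueError(f"bad value_kind {self.value_kind!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.value_kind == "numeric" and not self.unit_family:
            raise ValueError(f"numeric character {self.id} needs a unit family")


def _num(id, name, cat, extractor, units):
    return CharacterDef(id, name, cat, "numeric", extractor, unit_family=units)


def _cat(id, name, cat, extractor="term", partner=None, mode="phrase", neg=False):
    return CharacterDef(
        id, name, cat, "categorical", extractor,
        polarity_partner=partner, match_mode=mode, admits_negation=neg,
    )


CHARACTERS: tuple[CharacterDef, ...] = (
    _num("gc_content", "%G + C", "G + C Content", "gc", ("mol%",)),
    _cat("cell_shape", "Cell Shape", "Cell Morphology", mode="sentence"),
    _num("cell_diameter", "Cell Diameter", "Cell Morphology",
         "dimension:diameter", ("μm", "mm", "nm")),
    _num("cell_length", "Cell Length", "Cell Morphology",
         "dimension:length", ("μm", "mm", "nm")),
    _num("cell_width", "Cell Width", "Cell Morphology",
         "dimension:width", ("μm", "mm", "nm")),
    _cat("cell_aggregation", "Cell Relationships & Aggregations",
         "Cell Morphology"),
    _cat("gram_stain", "Gram Stain Type", "Cell Morphology", mode="sentence"),
    _cat("external_features", "External Features", "Cell Morphology"),
    _cat("internal_features", "Internal Features", "Cell Morphology", neg=True),
    _cat("motility", "Motility", "Cell Morphology", mode="sentence", neg=True),
    _cat("pigment_compounds", "Pigment Compounds", "Cell Morphology",
         mode="sentence"),
    _num("nacl_minimum", "NaCl Minimum", "Growth Condition",
         "triplet:nacl:minimum", ("%", "M", "g l−1")),
    _num("nacl_optimum", "NaCl Optimum", "Growth Condition",
         "triplet:nacl:optimum", ("%", "M", "g l−1")),
    _num("nacl_maximum", "NaCl Maximum", "Growth Condition",
         "triplet:nacl:maximum", ("%", "M", "g l−1")),
    _num("ph_minimum", "pH Minimum", "Growth Condition",
         "triplet:ph:minimum", ("pH",)),
    _num("ph_optimum", "pH Optimum", "Growth Condition",
         "triplet:ph:optimum", ("pH",)),
    _num("ph_maximum", "pH Maximum", "Growth Condition",
         "triplet:ph:maximum", ("pH",)),
    _num("temperature_minimum", "Temperature Minimum", "Growth Condition",
         "triplet:temperature:minimum", ("°C",)),
    _num("temperature_optimum", "Temperature Optimum", "Growth Condition",
         "triplet:temperature:optimum", ("°C",)),
    _num("temperature_maximum", "Temperature Maximum", "Growth Condition",
         "triplet:temperature:maximum", ("°C",)),
    _cat("salinity_requirement", "Salinity Requirement for Growth",
         "Growth Condition"),
    _cat("aerophilicity", "Aerophilicity", "Growth Condition", mode="sentence"),
    _cat("magnesium_requirement", "Magnesium Requirement for Growth",
         "Growth Condition"),
    _cat("vitamins_cofactors", "Vitamins and Cofactors Used For Growth",
         "Growth Condition"),
    _cat("antibiotic_sensitivity", "Antibiotic Sensitivity",
         "Antibiotic Physiology", extractor="pattern"),
    _cat("antibiotic_resistant", "Antibiotic Resistant",
         "Antibiotic Physiology", extractor="pattern"),
    _cat("colony_shape", "Colony Shape", "Colony Morphology", mode="sentence"),
    _cat("colony_margin", "Colony Margin", "Colony Morphology"),
    _cat("colony_texture", "Colony Texture", "Colony Morphology",
         mode="sentence"),
    _cat("colony_color", "Colony Color", "Colony Morphology", mode="sentence"),
    _cat("fermentation_products", "Fermentation Products",
         "Metabolic End Products and Secondary Metabolites"),
    _cat("other_metabolic_products", "Other Metabolic Products",
         "Metabolic End Products and Secondary Metabolites"),
    _cat("pathogenic", "Pathogenic", "Microbe-Host Interaction"),
    _cat("disease_caused", "Disease Caused", "Microbe-Host Interaction"),
    _cat("pathogen_target_organ", "Pathogen Target Organ",
         "Microbe-Host Interaction"),
    _cat("haemolytic", "Haemolytic/Haemadsorption Properties",
         "Microbe-Host Interaction", neg=True),
    _cat("organic_used", "Organic Compounds Used Or Hydrolyzed",
         "Metabolic Substrate", partner="organic_not_used"),
    _cat("organic_not_used", "Organic Compounds Not Used Or Not Hydrolyzed",
         "Metabolic Substrate", partner="organic_used"),
    _cat("inorganic_used", "Inorganic Substances Used",
         "Metabolic Substrate", partner="inorganic_not_used"),
    _cat("inorganic_not_used", "Inorganic Substances Not Used",
         "Metabolic Substrate", partner="inorganic_used"),
    _cat("fermentation_substrates_used", "Fermentation Substrates Used",
         "Metabolic Substrate", partner="fermentation_substrates_not_used"),
    _cat("fermentation_substrates_not_used", "Fermentation Substrates Not Used",
         "Metabolic Substrate", partner="fermentation_substrates_used"),
)

CHARACTERS_BY_ID: dict[str, CharacterDef] = {c.id: c for c in CHARACTERS}
CHARACTER_IDS: tuple[str, ...] = tuple(c.id for c in CHARACTERS)
DISPLAY_NAMES: tuple[str, ...] = tuple(c.display_name for c in CHARACTERS)
_BY_DISPLAY: dict[str, CharacterDef] = {c.display_name: c for c in CHARACTERS}

NUMERIC_IDS = tuple(c.id for c in CHARACTERS if c.value_kind == "numeric")


def get_character(id_or_name: str) -> CharacterDef:
    """Look a character up by id or by display name."""
    if id_or_name in CHARACTERS_BY_ID:
        return CHARACTERS_BY_ID[id_or_name]
    if id_or_name in _BY_DISPLAY:
        return _BY_DISPLAY[id_or_name]
    raise KeyError(f"unknown character: {id_or_name!r}")


assert len(CHARACTERS) == 42
assert len(set(DISPLAY_NAMES)) == 42
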