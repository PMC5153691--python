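{
  "DT": ["a", "an", "the", "no", "some", "most", "few", "this", "these",
         "that", "those", "each", "all", "any", "several"],
  "IN": ["in", "of", "from", "to", "at", "on", "by", "with", "for", "as",
         "under", "within", "into", "per", "between", "during", "after",
         "before", "above", "below", "than", "due"],
  "CC": ["and", "or", "but", "nor", "neither", "either"],
  "MD": ["can", "may", "will", "could", "might"],
  "VBZ": ["is", "has", "occurs", "grows", "requires", "produces", "ferments",
          "contains", "appears", "utilizes", "hydrolyzes", "forms", "does",
          "refers", "enhances"],
  "VBP": ["are", "have", "occur", "grow", "require", "produce", "ferment",
          "contain", "appear", "utilize", "hydrolyze", "form", "do",
          "enhance"],
  "VBD": ["was", "were", "occurred"],
  "VBN": ["produced", "observed", "used", "arranged", "formed", "isolated",
          "pigmented", "required", "detected", "found", "hydrolyzed",
          "fermented", "deposited", "determined", "infected", "utilized",
          "extracted", "grown", "stained"],
  "RB": ["not", "also", "often", "usually", "sometimes", "frequently",
         "singly", "optimally", "strictly", "obligately", "facultatively",
         "slightly", "extremely", "weakly", "strongly", "highly"],
  "JJ": ["motile", "non-motile", "anaerobic", "aerobic", "microaerophilic",
         "facultative", "long", "short", "slender", "small", "large", "wide",
         "convex", "circular", "irregular", "filamentous", "translucent",
         "smooth", "shiny", "golden-yellow", "yellow", "red", "orange",
         "pink", "brown", "white", "cream", "entire", "butyrous", "crooked",
         "cylindrical", "pleomorphic", "coccoid", "spiral-shaped",
         "rod-shaped", "punctiform", "sole", "positive", "negative",
         "sensitive", "resistant", "pathogenic", "optimal", "strict",
         "obligate", "plump", "old", "older", "new", "good", "hot", "marine",
         "natural", "experimental", "oral", "higher", "outer", "haemolytic",
         "gram-negative", "gram-positive", "gram-variable", "halophilic",
         "thermophilic", "spherical", "ovoid", "curved", "straight"],
  "NN": ["diameter", "length", "width", "content", "range", "optimum",
         "minimum", "maximum", "growth", "broth", "agar", "medium", "strain",
         "type", "cell", "colony", "chain", "pair", "cluster", "spore",
         "acid", "gas", "temperature", "edge", "margin", "consistency",
         "ph", "nacl", "salt", "water", "spring", "habitat", "collection",
         "culture", "name", "species", "glucose", "fructose", "sucrose",
         "maltose", "lactose", "mannose", "arabinose", "mannitol",
         "gluconate", "caprate", "adipate", "citrate", "malate", "salicin",
         "arbutin", "melibiose", "esculin", "lactate", "pyruvate",
         "glycerol", "erythritol", "ribose", "tetracycline", "rifampicin",
         "vancomycin", "streptomycin", "chloramphenicol", "kanamycin",
         "ampicillin", "erythromycin", "gentamicin", "penicillin",
         "acetoin", "methane", "ethanol", "haemin", "extract", "nitrate",
         "chloride", "nitrogen", "carbon", "energy", "source", "disc",
         "window", "μm", "mm", "nm", "mol%", "m"],
  "NNS": ["cells", "colonies", "chains", "pairs", "clusters", "spores",
          "rods", "cocci", "filaments", "elements", "strains", "sources",
          "compounds", "carbohydrates", "appendages", "sides", "ends",
          "vesicles", "granules", "temperatures", "salts", "carotenoids",
          "infections", "wounds", "humans", "honeybees", "hooves", "sheep",
          "goats", "substrates", "products", "media", "bacilli", "days",
          "endospores", "margins", "tests"]
}
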