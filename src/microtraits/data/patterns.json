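[
  {
    "name": "produced-from",
    "trigger": "produce",
    "voice": "passive",
    "requires_particle": "from",
    "role_map": {"nsubjpass": "fermentation_products",
                 "nmod": "fermentation_substrates_used"}
  },
  {
    "name": "produced-bare",
    "trigger": "produce",
    "voice": "passive",
    "forbids_particle": "from",
    "role_map": {"nsubjpass": "other_metabolic_products"}
  },
  {
    "name": "sensitive-to",
    "trigger": "sensitive",
    "voice": "adjective",
    "particle": "to",
    "role_map": {"pobj": "antibiotic_sensitivity"}
  },
  {
    "name": "resistant-to",
    "trigger": "resistant",
    "voice": "adjective",
    "particle": "to",
    "role_map": {"pobj": "antibiotic_resistant"}
  },
  {
    "name": "pathogenic-for",
    "trigger": "pathogenic",
    "voice": "adjective",
    "particle": "for",
    "role_map": {"pobj": "pathogenic"}
  },
  {
    "name": "requires-for-growth",
    "trigger": "require",
    "voice": "active",
    "context": "growth",
    "role_map": {"dobj": "salinity_requirement"},
    "filter_termlist": true
  },
  {
    "name": "requires-vitamins",
    "trigger": "require",
    "voice": "active",
    "context": "growth",
    "role_map": {"dobj": "vitamins_cofactors"},
    "filter_termlist": true
  },
  {
    "name": "required-for-growth",
    "trigger": "require",
    "voice": "passive",
    "context": "growth",
    "role_map": {"nsubjpass": "vitamins_cofactors"},
    "filter_termlist": true
  },
  {
    "name": "ferments",
    "trigger": "ferment",
    "voice": "active",
    "role_map": {"dobj": "fermentation_substrates_used"}
  }
]
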