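{
  "μm": ["μm", "µm", "um", "micron", "microns", "micrometer", "micrometers",
         "micrometre", "micrometres"],
  "mm": ["mm", "millimeter", "millimeters", "millimetre", "millimetres"],
  "nm": ["nm"],
  "°C": ["°C", "°c", "˚C", "degrees C", "deg C"],
  "mol%": ["mol%", "mol %"],
  "%": ["%", "percent", "per cent"],
  "M": ["M", "mol/l", "mol l−1", "mol l-1"],
  "g l−1": ["g l−1", "g l-1", "g/l", "g per liter", "g per litre"],
  "pH": ["pH"]
}
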