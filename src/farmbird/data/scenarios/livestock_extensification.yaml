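# Livestock extensification: extensive, grass-based production in livestock
# and mixed-farming regions (more grassland, less forage maize); arable
# regions mimic current cropping patterns (no constraints, shares unchanged).
# Interpretive defaults beyond the narrative direction of change.
name: livestock_extensification
transitions:
  arable: arable
  livestock: livestock_extensive
  mixed: mixed_extensive
constraints:
  arable: {}
  livestock_extensive:
    lower:
      permanent_grassland: {rel: 1.2, cap: 0.95}
      temporary_grassland: {rel: 1.0}
    upper:
      corn_fodder: {rel: 0.7}
  mixed_extensive:
    lower:
      permanent_grassland: {rel: 1.15, cap: 0.9}
    upper:
      corn_fodder: {rel: 0.8}
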