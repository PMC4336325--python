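# Global (national) biofuel: bioenergy cropping expands uniformly across all
# agroecosystems. COP crops (cereals, oleaginous, proteaginous) rise in most
# regions at the expense of grasslands and forage crops.
# Interpretive defaults beyond the narrative direction of change.
name: global_biofuel
transitions:
  arable: arable
  livestock: livestock
  mixed: mixed
constraints:
  arable: &biofuel
    groups:
      - crops: [cereals, grain_maize, rapeseed, sunflower, proteaginous]
        min: {rel: 1.0, shift: 0.10, cap: 0.9}
    upper:
      permanent_grassland: {rel: 0.85}
      temporary_grassland: {rel: 0.9}
      forage_crops: {rel: 0.85}
  livestock: *biofuel
  mixed: *biofuel
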