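# Regional biofuel: COP expansion is concentrated in arable and mixed-farming
# regions (which specialize further into crops), balanced by grassland
# extensification in livestock regions.
# Interpretive defaults beyond the narrative direction of change.
name: regional_biofuel
transitions:
  arable: crop_specialized
  mixed: crop_specialized
  livestock: extensive_grassland
constraints:
  crop_specialized:
    groups:
      - crops: [cereals, grain_maize, rapeseed, sunflower, proteaginous]
        min: {rel: 1.0, shift: 0.15, cap: 0.9}
    upper:
      permanent_grassland: {rel: 0.8}
      temporary_grassland: {rel: 0.85}
  extensive_grassland:
    lower:
      permanent_grassland: {rel: 1.15, cap: 0.95}
    upper:
      corn_fodder: {rel: 0.7}
      grain_maize: {rel: 1.0}
      rapeseed: {rel: 1.0}
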