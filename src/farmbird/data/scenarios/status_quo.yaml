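# Status quo: current agricultural trends continue to 2050. Grasslands,
# especially permanent grassland, keep shrinking nationally; cereal dominance
# and grain-fed livestock (forage maize) persist or grow.
# Interpretive defaults: only the direction of each change is narratively
# pinned; the multipliers are this package's reading and are meant to be edited.
name: status_quo
transitions:
  arable: arable
  livestock: livestock
  mixed: mixed
constraints:
  arable: &trend
    upper:
      permanent_grassland: {rel: 0.85}
      temporary_grassland: {rel: 0.95}
      forage_crops: {rel: 0.9}
    lower:
      corn_fodder: {rel: 1.0}
    groups:
      - crops: [cereals, grain_maize, rapeseed, sunflower, proteaginous]
        min: {rel: 1.0}
  livestock: *trend
  mixed: *trend
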