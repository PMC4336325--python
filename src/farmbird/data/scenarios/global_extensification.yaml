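# Global extensification: a uniform national framework imposing a minimum of
# 5% permanent grassland everywhere. Livestock and mixed regions expand
# pasture and cut forage maize; arable regions trim COP crops and diversify
# rotations with proteaginous crops.
# The 5% permanent-grassland floor is narratively pinned; other multipliers
# are interpretive defaults.
name: global_extensification
transitions:
  arable: arable
  livestock: livestock
  mixed: mixed
constraints:
  arable:
    lower:
      permanent_grassland: {abs: 0.05}
      proteaginous: {rel: 1.2, cap: 0.2}
    groups:
      - crops: [cereals, grain_maize, rapeseed, sunflower, proteaginous]
        max: {rel: 0.95}
  livestock:
    lower:
      permanent_grassland: {rel: 1.2, cap: 0.95, floor: 0.05}
    upper:
      corn_fodder: {rel: 0.8}
      forage_crops: {rel: 0.9}
  mixed:
    lower:
      permanent_grassland: {rel: 1.15, cap: 0.9, floor: 0.05}
    upper:
      corn_fodder: {rel: 0.85}
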