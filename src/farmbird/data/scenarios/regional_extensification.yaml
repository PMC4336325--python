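# Regional extensification: arable and mixed regions diversify rotations —
# no single crop may exceed 45% of the agricultural area — with modest
# grassland loss; livestock regions expand permanent grassland at the
# expense of all other crops.
# The 45% primary-crop cap is narratively pinned; other multipliers are
# interpretive defaults.
name: regional_extensification
transitions:
  arable: arable_diversified
  mixed: mixed_diversified
  livestock: extensive_grassland
constraints:
  arable_diversified:
    primary_crop_cap: 0.45
    lower:
      proteaginous: {rel: 1.1, cap: 0.2}
    upper:
      permanent_grassland: {rel: 0.9}
  mixed_diversified:
    primary_crop_cap: 0.45
    lower:
      proteaginous: {rel: 1.1, cap: 0.2}
    upper:
      permanent_grassland: {rel: 0.9}
  extensive_grassland:
    lower:
      permanent_grassland: {rel: 1.2, cap: 0.95}
    upper:
      temporary_grassland: {rel: 1.0}
      cereals: {rel: 1.0}
      grain_maize: {rel: 1.0}
      rapeseed: {rel: 1.0}
      sunflower: {rel: 1.0}
      corn_fodder: {rel: 1.0}
      proteaginous: {rel: 1.0}
      forage_crops: {rel: 1.0}
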