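# WIC-style vendor requirements: high enforcement everywhere, with the
# required depth of stock varying from moderate to high by food.  The
# targeted foods that carry the high requirement default to the
# longest-shelf-life half of the catalog, so that deep required stocks
# sit on foods that can hold them without spoiling.
name: wic
description: WIC vendor stocking requirements
stock: moderate
enforcement: high
targeted_stock: high
targets: least_perishable_half
promotions:
  training: 5
  signage: 5
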