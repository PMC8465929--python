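# SNAP Minimum: the minimal stocking requirements a store must meet to
# accept SNAP benefits.  Low required depth of stock, moderate enforcement.
name: snap_minimum
description: SNAP minimum stocking requirements
stock: low
enforcement: moderate
promotions:
  training: 5
  signage: 5
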