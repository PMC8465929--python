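# SNAP Depth: the 2016 proposed enhanced depth-of-stock requirements.
# High required stock for every food, high enforcement.
name: snap_depth
description: SNAP proposed enhanced depth-of-stock requirements
stock: high
enforcement: high
promotions:
  training: 5
  signage: 5
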