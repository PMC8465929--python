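# Minneapolis-style staple food ordinance: moderate required stock but
# low enforcement, leaving stocking effectively demand-driven.
name: minneapolis
description: Minneapolis staple food ordinance requirements
stock: moderate
enforcement: low
promotions:
  training: 5
  signage: 5
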