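# default whole-milk composition, g per 100 g, v1
water: 87.0
lactose: 4.8
fat: 3.7
protein: 3.3
ash: 0.7
nacl: 0.1
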