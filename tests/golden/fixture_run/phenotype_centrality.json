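{
 "FVC": 13,
 "stiffness_index": 21
}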