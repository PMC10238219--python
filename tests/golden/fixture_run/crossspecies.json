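{
 "cohort1_same_trend_pct": 64.71,
 "cohort2_same_trend_pct": 73.68,
 "validated_n": 8
}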