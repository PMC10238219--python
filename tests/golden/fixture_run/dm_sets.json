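{
 "DM-0": [
  "met_005",
  "met_006",
  "met_007",
  "met_008",
  "met_009",
  "met_010"
 ],
 "DM-1": [
  "met_001",
  "met_002",
  "met_003"
 ],
 "removed_by_missingness": [
  "met_004",
  "met_011"
 ]
}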