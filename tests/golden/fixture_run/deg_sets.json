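{
 "DEG-0": [],
 "DEG-1": [
  "gene_0002",
  "gene_0003",
  "gene_0004",
  "gene_0005",
  "gene_0006",
  "gene_0007",
  "gene_0029",
  "gene_0030"
 ]
}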