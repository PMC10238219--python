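gcn_label	mcn_label	subsystem	padj_gene	padj_metab
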