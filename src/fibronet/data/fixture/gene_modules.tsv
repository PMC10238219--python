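gene	module
gene_0001	0
gene_0002	0
gene_0003	0
gene_0004	0
gene_0005	0
gene_0006	0
gene_0007	0
gene_0008	0
gene_0009	1
gene_0010	1
gene_0011	1
gene_0012	1
gene_0013	1
gene_0014	1
gene_0015	1
gene_0016	1
gene_0017	2
gene_0018	2
gene_0019	2
gene_0020	2
gene_0021	2
gene_0022	2
gene_0023	2
gene_0024	2
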