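node	kind	subnetwork	degree	local_cc
gene_0009	gene	0	7	0.7142857142857143
gene_0013	gene	0	6	0.8
gene_0011	gene	0	6	0.8
gene_0015	gene	0	6	0.8
gene_0010	gene	0	4	0.8333333333333334
gene_0012	gene	0	6	0.7333333333333333
gene_0005	gene	1	4	0.8333333333333334
gene_0006	gene	1	5	0.7
gene_0026	gene	4	2	1.0
gene_0029	gene	4	3	0.6666666666666666
gene_0014	gene	0	4	1.0
gene_0016	gene	0	5	0.8
gene_0002	gene	2	3	1.0
gene_0007	gene	2	4	0.8333333333333334
gene_0003	gene	1	4	0.8333333333333334
gene_0030	gene	1	3	1.0
gene_0027	gene	1	3	1.0
gene_0004	gene	1	3	1.0
gene_0018	gene	3	2	1.0
gene_0022	gene	3	2	1.0
gene_0025	gene	2	3	1.0
gene_0001	gene	5	2	1.0
stiffness_index	phenotype	3	22	0.08658008658008658
FVC	phenotype	1	14	0.21978021978021978
gene_0008	gene	6	2	1.0
gene_0017	gene	7	1	0.0
gene_0019	gene	8	1	0.0
gene_0020	gene	9	1	0.0
gene_0021	gene	10	1	0.0
gene_0023	gene	11	1	0.0
gene_0024	gene	12	1	0.0
gene_0028	gene	13	1	0.0
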