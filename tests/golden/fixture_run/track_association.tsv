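track	subnetwork	overlap	track_size	subnetwork_size	universe_size	pvalue	padj
T-1	0	0	8	8	30	1.0	1.0
T-1	1	4	8	6	30	0.029354553492484524	0.616445623342175
T-1	2	2	8	3	30	0.16551724137931031	0.9333333333333333
T-1	3	0	8	2	30	1.0	1.0
T-1	4	0	8	2	30	1.0	1.0
T-1	5	1	8	1	30	0.26666666666666666	0.9333333333333333
T-1	6	1	8	1	30	0.26666666666666666	0.9333333333333333
T-1	7	0	8	1	30	1.0	1.0
T-1	8	0	8	1	30	1.0	1.0
T-1	9	0	8	1	30	1.0	1.0
T-1	10	0	8	1	30	1.0	1.0
T-1	11	0	8	1	30	1.0	1.0
T-1	12	0	8	1	30	1.0	1.0
T-1	13	0	8	1	30	1.0	1.0
T-2	0	8	8	8	30	1.7085474356838674e-07	7.175899229872244e-06
T-2	1	0	8	6	30	1.0	1.0
T-2	2	0	8	3	30	1.0	1.0
T-2	3	0	8	2	30	1.0	1.0
T-2	4	0	8	2	30	1.0	1.0
T-2	5	0	8	1	30	1.0	1.0
T-2	6	0	8	1	30	1.0	1.0
T-2	7	0	8	1	30	1.0	1.0
T-2	8	0	8	1	30	1.0	1.0
T-2	9	0	8	1	30	1.0	1.0
T-2	10	0	8	1	30	1.0	1.0
T-2	11	0	8	1	30	1.0	1.0
T-2	12	0	8	1	30	1.0	1.0
T-2	13	0	8	1	30	1.0	1.0
T-3	0	0	8	8	30	1.0	1.0
T-3	1	0	8	6	30	1.0	1.0
T-3	2	0	8	3	30	1.0	1.0
T-3	3	2	8	2	30	0.06436781609195402	0.9011494252873563
T-3	4	0	8	2	30	1.0	1.0
T-3	5	0	8	1	30	1.0	1.0
T-3	6	0	8	1	30	1.0	1.0
T-3	7	1	8	1	30	0.26666666666666666	0.9333333333333333
T-3	8	1	8	1	30	0.26666666666666666	0.9333333333333333
T-3	9	1	8	1	30	0.26666666666666666	0.9333333333333333
T-3	10	1	8	1	30	0.26666666666666666	0.9333333333333333
T-3	11	1	8	1	30	0.26666666666666666	0.9333333333333333
T-3	12	1	8	1	30	0.26666666666666666	0.9333333333333333
T-3	13	0	8	1	30	1.0	1.0
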