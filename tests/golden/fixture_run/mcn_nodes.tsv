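node	kind	subnetwork	degree	local_cc
met_001	metabolite	0	5	1.0
met_002	metabolite	1	8	0.5357142857142857
met_003	metabolite	0	7	0.6190476190476191
met_008	metabolite	0	5	1.0
met_009	metabolite	0	5	1.0
met_010	metabolite	0	5	1.0
met_005	metabolite	1	4	0.8333333333333334
met_006	metabolite	1	4	0.8333333333333334
met_007	metabolite	1	4	0.5
met_012	metabolite	1	1	0.0
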