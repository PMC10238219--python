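metabolite	module
met_001	0
met_002	0
met_003	0
met_004	0
met_005	1
met_006	1
met_007	1
met_008	2
met_009	2
met_010	2
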