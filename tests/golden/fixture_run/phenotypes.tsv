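feature	control_1	control_2	control_3	d7_1	d7_2	d7_3	d14_1	d14_2	d14_3	d21_1	d21_2	d21_3	d28_1	d28_2	d28_3
stiffness_index	0.0	0.0	0.0	0.6	0.6	0.6	1.8	1.8	1.8	1.5	1.5	1.5	1.4	1.4	1.4
FVC	-0.022031604369484738	0.03243885235601083	-0.24014544345928718	-1.2933466738413086	-1.0327240927246117	-0.791741613068117	-1.9934800646495725	-1.7709893198371278	-2.083971412297258	-1.4057215389973199	-1.5407002484985082	-1.735438430269481	-0.9551790136735381	-0.6990257295054745	-0.947626093443882
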