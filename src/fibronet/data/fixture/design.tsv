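sample	group
control_1	control
control_2	control
control_3	control
d7_1	d7
d7_2	d7
d7_3	d7
d14_1	d14
d14_2	d14
d14_3	d14
d21_1	d21
d21_2	d21
d21_3	d21
d28_1	d28
d28_2	d28
d28_3	d28
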