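subnetwork	n_members	n_dysregulated	n_reversed	reversed_fraction	pvalue	padj	call
0	8	3	2	0.6666666666666666	0.9436820051512705	1.0	unchanged
1	6	6	5	0.8333333333333334	0.3263862574207402	1.0	unchanged
2	3	3	3	1.0	0.28078817733990147	1.0	unchanged
3	2	1	1	1.0	0.4367816091954023	1.0	unchanged
4	2	2	1	0.5	0.896551724137931	1.0	unchanged
5	1	1	1	1.0	0.6666666666666667	1.0	unchanged
6	1	1	1	1.0	0.6666666666666667	1.0	unchanged
7	1	1	1	1.0	0.6666666666666667	1.0	unchanged
8	1	0	0	0.0	1.0	1.0	unchanged
9	1	0	0	0.0	0.6666666666666667	1.0	unchanged
10	1	0	0	0.0	1.0	1.0	unchanged
11	1	0	0	0.0	1.0	1.0	unchanged
12	1	0	0	0.0	1.0	1.0	unchanged
13	1	1	1	1.0	0.6666666666666667	1.0	unchanged
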