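source	target	rho	pvalue	padj
met_001	met_002	0.6392857142857141	0.010288446619594209	0.023149004894086972
met_001	met_003	0.7964285714285713	0.00038046767853463354	0.001712104553405851
met_001	met_008	-0.825	0.0001532355709056458	0.0008619500863442576
met_001	met_009	-0.8571428571428571	4.446004447004746e-05	0.0005001755002880339
met_001	met_010	-0.8428571428571429	7.96719525272486e-05	0.0005873744472762816
met_002	met_003	0.8857142857142855	1.1199821851208482e-05	0.00025199599165219084
met_002	met_005	-0.7428571428571428	0.0015094888782350333	0.004245437470036031
met_002	met_006	-0.7571428571428571	0.0010811081941858344	0.004054155728196879
met_002	met_007	-0.6	0.018050087941499978	0.036920634425795414
met_002	met_008	-0.7428571428571428	0.0015094888782350333	0.004245437470036031
met_002	met_009	-0.7392857142857142	0.001635511143540766	0.004329294203490263
met_002	met_010	-0.5821428571428571	0.02279368712641428	0.04459634437776707
met_003	met_005	-0.6928571428571427	0.004190232960298139	0.009924235958600855
met_003	met_006	-0.7178571428571427	0.0025811653082188565	0.006452913270547141
met_003	met_008	-0.7464285714285712	0.001391411089063054	0.004245437470036031
met_003	met_009	-0.782142857142857	0.0005697096277734964	0.002330630295437031
met_003	met_010	-0.6321428571428571	0.0114575415400789	0.0245518747287405
met_005	met_006	0.9428571428571427	1.4247676947645738e-07	6.4114546264405815e-06
met_005	met_007	0.8499999999999999	5.9958885253110194e-05	0.0005396299672779918
met_006	met_007	0.8392857142857142	9.136935846519936e-05	0.0005873744472762816
met_007	met_012	0.575	0.02493622794258254	0.046755427392342265
met_008	met_009	0.8642857142857141	3.243373143346799e-05	0.00048650597150201987
met_008	met_010	0.7499999999999999	0.0012808984509355362	0.004245437470036031
met_009	met_010	0.8214285714285712	0.0001731477175071704	0.0008657385875358519
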