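source	target	rho	pvalue	padj
gene_0009	gene_0013	0.9749999999999999	7.143705965229251e-10	1.7716390793768542e-07
gene_0009	gene_0011	0.9607142857142855	1.3027489790343458e-08	1.6154087340025887e-06
gene_0011	gene_0015	0.9607142857142855	1.3027489790343458e-08	1.6154087340025887e-06
gene_0010	gene_0012	0.9571428571428571	2.2736751556259772e-08	2.2554857543809696e-06
gene_0011	gene_0013	0.9392857142857142	2.0945801936685522e-07	1.4330288312396758e-05
gene_0005	gene_0006	0.932142857142857	4.241218231543346e-07	2.1036442428454997e-05
gene_0009	gene_0015	0.932142857142857	4.241218231543346e-07	2.1036442428454997e-05
gene_0013	gene_0015	0.9249999999999998	7.987462113818486e-07	3.601619280412699e-05
gene_0026	gene_0029	0.9214285714285713	1.0713172981620741e-06	4.428111499069906e-05
gene_0009	gene_0012	0.914285714285714	1.8531121308926476e-06	7.070335514790409e-05
gene_0011	gene_0014	0.9035714285714285	3.880504128799778e-06	0.00012029562799279312
gene_0012	gene_0013	0.9035714285714285	3.880504128799778e-06	0.00012029562799279312
gene_0009	gene_0016	0.8964285714285712	6.066143021729967e-06	0.00015835825993568758
gene_0002	gene_0007	0.8892857142857141	9.192974758842262e-06	0.0002171293085897982
gene_0011	gene_0016	0.8892857142857141	9.192974758842262e-06	0.0002171293085897982
gene_0009	gene_0010	0.8857142857142855	1.1199821851208482e-05	0.0002314629849249753
gene_0013	gene_0016	0.8857142857142855	1.1199821851208482e-05	0.0002314629849249753
gene_0010	gene_0013	0.8821428571428571	1.3558210624788723e-05	0.0002490693507368595
gene_0011	gene_0012	0.8821428571428571	1.3558210624788723e-05	0.0002490693507368595
gene_0012	gene_0014	0.8821428571428571	1.3558210624788723e-05	0.0002490693507368595
gene_0012	gene_0015	0.8785714285714284	1.631528028654429e-05	0.00026974596740419896
gene_0014	gene_0015	0.8785714285714284	1.631528028654429e-05	0.00026974596740419896
gene_0003	gene_0030	0.8749999999999999	1.9522613815941113e-05	0.00029343080159717553
gene_0006	gene_0027	0.8749999999999999	1.9522613815941113e-05	0.00029343080159717553
gene_0010	gene_0016	0.8749999999999999	1.9522613815941113e-05	0.00029343080159717553
gene_0004	gene_0006	0.8714285714285712	2.323647782163262e-05	0.00031149440539269673
gene_0015	gene_0016	0.8714285714285712	2.323647782163262e-05	0.00031149440539269673
gene_0018	gene_0022	0.8714285714285712	2.323647782163262e-05	0.00031149440539269673
gene_0007	gene_0025	0.8678571428571429	2.7518063955129214e-05	0.00034997332619856643
gene_0009	gene_0014	0.8678571428571429	2.7518063955129214e-05	0.00034997332619856643
gene_0003	gene_0005	0.8642857142857141	3.243373143346799e-05	0.00037411932072093306
gene_0001	stiffness_index	-0.7201190377787748	0.0024644721244400456	0.010186484781018855
gene_0001	FVC	0.6607142857142856	0.007330569830891709	0.023012421747609417
gene_0002	stiffness_index	-0.9383369280147673	2.3113368245801223e-07	1.4330288312396758e-05
gene_0002	FVC	0.8857142857142855	1.1199821851208482e-05	0.0002314629849249753
gene_0003	stiffness_index	-0.829227982896771	0.00013213472945083739	0.0011565760507905836
gene_0003	FVC	0.8999999999999999	4.871970948735605e-06	0.0001421469170925212
gene_0004	stiffness_index	-0.774673510337773	0.0006955821023620977	0.0038334302530177826
gene_0004	FVC	0.8392857142857142	9.136935846519936e-05	0.0008392444777544238
gene_0005	stiffness_index	-0.8728715609439696	2.1671149381871683e-05	0.00031149440539269673
gene_0005	FVC	0.95	6.086257958053973e-08	5.031306578657952e-06
gene_0006	stiffness_index	-0.7855844048495726	0.0005183176017156384	0.003213569130636958
gene_0006	FVC	0.8642857142857141	3.243373143346799e-05	0.00037411932072093306
gene_0007	stiffness_index	-0.9819805060619657	8.648244862274892e-11	4.289529451688347e-08
gene_0007	FVC	0.8964285714285712	6.066143021729967e-06	0.00015835825993568758
gene_0008	stiffness_index	-0.7964952993613723	0.0003797234163787197	0.0025850954596325785
gene_0008	FVC	0.807142857142857	0.00027524427069541943	0.0019503022609275431
gene_0017	stiffness_index	0.7528517213141738	0.0011978412625517812	0.005768245303161975
gene_0018	stiffness_index	0.7419408268023742	0.0015410491421319259	0.00701248049997647
gene_0019	stiffness_index	0.7528517213141738	0.0011978412625517812	0.005768245303161975
gene_0020	stiffness_index	0.7855844048495726	0.0005183176017156384	0.003213569130636958
gene_0021	stiffness_index	0.6219209871725783	0.01330739166538025	0.0367259410455369
gene_0022	stiffness_index	0.687386354243376	0.00463058471129697	0.01640550012002355
gene_0023	stiffness_index	0.7310299322905744	0.0019594051507816346	0.008236143684641447
gene_0024	stiffness_index	0.6546536707079772	0.008088745097244995	0.024919363777847935
gene_0025	stiffness_index	-0.8510497719203702	5.743579984302298e-05	0.0005935032650445708
gene_0025	FVC	0.8785714285714284	1.631528028654429e-05	0.00026974596740419896
gene_0026	FVC	0.6071428571428571	0.01638130676830708	0.04368348471548555
gene_0027	stiffness_index	-0.8074061938731718	0.00027299584756362	0.0019503022609275431
gene_0027	FVC	0.7321428571428571	0.0019129636009785618	0.008109657658849287
gene_0028	stiffness_index	-0.6328318816843779	0.011340463586176746	0.03232683872841187
gene_0029	stiffness_index	-0.6219209871725783	0.01330739166538025	0.0367259410455369
gene_0029	FVC	0.7035714285714285	0.0034243370890839593	0.012965428978516366
gene_0030	stiffness_index	-0.8183170883849714	0.00019218257412988374	0.001489041959128408
gene_0030	FVC	0.7642857142857141	0.0009073101116849783	0.004639441395832466
stiffness_index	FVC	-0.9056042444793685	3.3956945865065634e-06	0.00012029562799279312
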