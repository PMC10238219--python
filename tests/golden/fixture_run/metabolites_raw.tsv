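feature	control_1	control_2	control_3	d7_1	d7_2	d7_3	d14_1	d14_2	d14_3	d21_1	d21_2	d21_3	d28_1	d28_2	d28_3
met_001	7.5657050853502055	7.442144663992489	5.565184839311351	3.5245087619383297	4.457469264601108	3.047623925112574	1.192828085413998	1.0927030905866313	1.2381289339809936	1.7704245809344066	1.520261675614553	3.2489944058980385	2.649982100350798	1.9051558633824277	2.238991836412569
met_002	29.015857870748412	46.114849806544775	23.728842999747616	6.981066510062282	7.945098503931511	8.908252665000104	3.3096027333658307	1.6446043417242246	3.2653594078918613	6.077802399201431	8.95971513869493	2.9671912307824373	9.399272597481055	14.166398360624754	11.271663423565274
met_003	23.99322285285273	25.350444926420963	36.2447499473841	8.027095362989105	5.963011653050375	7.99189970130509	2.4872747237272597	2.3481214445854626	4.51443034274036	4.623507629716283	5.194166148146921	6.077005448459877	9.509671624888792	9.566629481259342	8.052251209525878
met_004	3.667162486163722	3.120424717801636	4.835759243710854	1.3114956074275181	1.8264037517060725	1.0294719987698764				0.8379461415917165	0.5364662832879362	0.4636464008623802	1.6948758472916996	0.9713979023486772	1.7043918259298023
met_005	15.795844295623978	14.392033806858237	19.769279161836646	254.36658804452387	201.5016611210864	302.65668878192776	136.20336750367443	153.8981232805281	174.91081047065256	51.09946986497757	34.80188980743941	44.152642131237066	26.975536991865845	24.332053013479165	29.210101112228525
met_006	2.196515675078505	2.9432646840279233	5.8642130591648876	13.624729317323903	31.23890998228304	23.886074611435415	13.610603804156643	15.618448763759755	21.57226388285801	8.886083177602144	6.904042900074679	7.745143199633482	6.143995924869519	4.464539192874218	3.1647213913350702
met_007	3.5382248769288767	8.857227128331754	3.3924135123428516	58.005071751156855	44.25611070596362	75.88404987399078	27.747149454249808	34.507419934983126	32.96713725954366	7.615173464998217	7.590014974810266	8.214503976621126	5.64631643581426	4.938578498530772	4.465521985364116
met_008		0.5256861448381591	0.8190433334692335	0.9406986640720612	1.2858877905185895	1.0844634083552966	3.7503075839624214	4.475947949689743	4.889652759498406	5.170715653934138	3.5039807492291635	4.138798892340264	3.0337200428759252	3.7630512615909626	2.4418754240016485
met_009	20.05431464526562	15.148994509874175	18.204112586751744	24.985494002489684	29.102706218504675	26.4121033108311	122.75591889505347	92.22496007889403	125.7713272988586	71.72114918628301	60.392740820309754	61.350680592645936	85.50773916668288	57.5087295688602	60.59166488316571
met_010	9.85867462160907	10.374624982476318	14.612628441270111	19.040125239265365	13.356123354145227	11.427622752061586	51.82182221485264	43.210833939140585	58.69764442229986	23.71195215785215	36.975598345362414	31.484577979424476	23.670069423785726	31.342860746265618	57.66498840468812
met_011				0.9833723020785761		0.6256188683176936	1.2535118962850968				0.4878361597243861	0.7452818487477242	0.7494777379507273	0.885938024032904	
met_012	0.8073632233815224	1.139241366249622	0.8679661730019267	1.5872150552888482	1.1389510562089795	1.5853575443204633	0.8498794468045404	1.1573438688904465	1.3304659913184667	1.2339887592890904	1.6151161763395705	0.7528539030239408	0.9306666152246956	0.8576940178192385	0.6575635867559941
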