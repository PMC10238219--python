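feature	log2fc	pvalue	padj	contrast
gene_0001	-3.057246291451121	0.031865369653036255	0.05031374155742567	d7_vs_control
gene_0002	-2.2503350441815417	0.00011964069876564005	0.0017946104814846008	d7_vs_control
gene_0003	-2.786547585898269	0.0019586284984907444	0.005341714086792939	d7_vs_control
gene_0004	-2.646029806928122	0.0035257061191908625	0.007949228560391425	d7_vs_control
gene_0005	-2.8102472570764574	0.0005436560421000578	0.003124656185434933	d7_vs_control
gene_0006	-2.9505635152965004	8.79862616522879e-05	0.0017946104814846008	d7_vs_control
gene_0007	-2.5909632182173477	0.0004838782151068238	0.003124656185434933	d7_vs_control
gene_0008	-2.388926615516853	0.03689076462079792	0.05514554892830369	d7_vs_control
gene_0009	2.1666915600122465	0.000729086443268151	0.003124656185434933	d7_vs_control
gene_0010	2.1685497874751487	0.0014107136330610078	0.004702378776870026	d7_vs_control
gene_0011	2.229167342331534	0.0006701628014465623	0.003124656185434933	d7_vs_control
gene_0012	2.197198265413732	0.0026299090689477014	0.006574772672369254	d7_vs_control
gene_0013	2.74259476542011	0.00020456125985774686	0.0020456125985774684	d7_vs_control
gene_0014	1.8187654574379248	0.004004954477073409	0.007949228560391425	d7_vs_control
gene_0015	2.1906034615278855	0.0017221926719909013	0.005166578015972704	d7_vs_control
gene_0016	2.492466137549564	0.0009606431558527697	0.0036024118344478865	d7_vs_control
gene_0017	-0.21894908095835763	0.26222910585271125	0.3146749270232535	d7_vs_control
gene_0018	0.14423574485295187	0.4005597007944644	0.44506633421607156	d7_vs_control
gene_0019	0.41064903026376154	0.18493172086503862	0.23116465108129827	d7_vs_control
gene_0020	0.4195392553307453	0.4002128056850642	0.44506633421607156	d7_vs_control
gene_0021	0.41970676615222935	0.13105455903653568	0.17094072917809	d7_vs_control
gene_0022	0.4336089959499638	0.44992781495415896	0.4820655160223132	d7_vs_control
gene_0023	-0.06390443036849991	0.7053104135605313	0.7296314623039979	d7_vs_control
gene_0024	0.03299558104102118	0.9091558226395423	0.9091558226395423	d7_vs_control
gene_0025	-1.2178155406987905	0.03860188424981258	0.05514554892830369	d7_vs_control
gene_0026	-1.2579929668626813	0.02301742449621871	0.038879825614529066	d7_vs_control
gene_0027	-0.8525603715637962	0.049981920590211296	0.06815716444119722	d7_vs_control
gene_0028	-1.297928644635629	0.02332789536871744	0.038879825614529066	d7_vs_control
gene_0029	-1.5123198388994359	0.003902603657962521	0.007949228560391425	d7_vs_control
gene_0030	-0.9258151822602088	0.004239588565542093	0.007949228560391425	d7_vs_control
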