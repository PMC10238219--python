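feature	log2fc	pvalue	padj	contrast
gene_0001	-4.2212617444912715	0.0005483882765074462	0.002350235470746198	d14_vs_control
gene_0002	-4.509219405598497	3.6096172264372215e-05	0.0006645590133799521	d14_vs_control
gene_0003	-4.601530044859087	0.0006802044942841837	0.002550766853565689	d14_vs_control
gene_0004	-4.056098996970145	4.430393422533014e-05	0.0006645590133799521	d14_vs_control
gene_0005	-4.82798439770128	9.389347590974947e-05	0.0009389347590974946	d14_vs_control
gene_0006	-4.6618124364909255	0.0046309521070840125	0.012330048848020636	d14_vs_control
gene_0007	-4.718288738886764	0.00013399181975890583	0.0010049386481917938	d14_vs_control
gene_0008	-3.593189804020302	0.010751613103301038	0.020159274568689448	d14_vs_control
gene_0009	1.194893797198814	0.046915858559314086	0.058644823199142604	d14_vs_control
gene_0010	0.6764511771330284	0.06525571393477785	0.07830685672173342	d14_vs_control
gene_0011	1.2046470473815827	0.011486565695581819	0.020234337181137953	d14_vs_control
gene_0012	0.9680491138252219	0.04417646304467171	0.05829801442697009	d14_vs_control
gene_0013	1.3620004131369594	0.0010556118287730625	0.0035187060959102085	d14_vs_control
gene_0014	0.6827979690841239	0.10347423247987782	0.10347423247987782	d14_vs_control
gene_0015	0.5769242421843526	0.09433611447418552	0.0975890839388126	d14_vs_control
gene_0016	0.706954084995516	0.007479162050927311	0.017003111052003642	d14_vs_control
gene_0017	1.378614055877149	0.0014964881496625424	0.004489464448987628	d14_vs_control
gene_0018	1.2904283516495942	0.004932019539208255	0.012330048848020636	d14_vs_control
gene_0019	1.1900175272804399	0.03662004684087445	0.05493007026131168	d14_vs_control
gene_0020	1.475367877752097	0.04469514439401041	0.05829801442697009	d14_vs_control
gene_0021	0.6924119730857319	0.03918385049211551	0.05597692927445073	d14_vs_control
gene_0022	1.4775437476544644	0.0704196215540341	0.08125340948542395	d14_vs_control
gene_0023	0.9058165094300463	0.09400755913318544	0.0975890839388126	d14_vs_control
gene_0024	0.8272429404713186	0.07812929668874043	0.08681032965415603	d14_vs_control
gene_0025	-1.951658498804198	0.01064948497056874	0.020159274568689448	d14_vs_control
gene_0026	-1.4168935994202938	0.020274641640700836	0.03201259206426448	d14_vs_control
gene_0027	-1.5630449335584702	0.0079347851576017	0.017003111052003642	d14_vs_control
gene_0028	-2.1376570162828195	0.01214060230868277	0.020234337181137953	d14_vs_control
gene_0029	-1.8385223466935923	0.0003525595047294188	0.001762797523647094	d14_vs_control
gene_0030	-1.949493614168305	0.0003346098718357834	0.001762797523647094	d14_vs_control
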