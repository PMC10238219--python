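feature	log2fc	pvalue	padj	contrast
gene_0001	-3.0239105506565016	0.0029092550166346935	0.01140826206835404	d28_vs_control
gene_0002	-2.32928229765567	0.007034040844524814	0.017585102111312034	d28_vs_control
gene_0003	-2.4737565113596904	0.005493035143625621	0.01585140954850316	d28_vs_control
gene_0004	-1.9416636909017244	0.00011787123481174342	0.0035361370443523026	d28_vs_control
gene_0005	-2.488121765794703	0.0058121835011178255	0.01585140954850316	d28_vs_control
gene_0006	-2.583398140111731	0.002946862952082814	0.01140826206835404	d28_vs_control
gene_0007	-2.8591408853298823	0.0008691077339760578	0.009720475161644017	d28_vs_control
gene_0008	-3.106594720947904	0.014107590036111261	0.028215180072222523	d28_vs_control
gene_0009	-0.6187688349098224	0.01922155414140309	0.03604041401513079	d28_vs_control
gene_0010	-1.1501783607805143	0.03351097313519426	0.04569678154799217	d28_vs_control
gene_0011	-0.7453268728680662	0.026570511600265963	0.03985576740039895	d28_vs_control
gene_0012	-0.9750408406395579	0.031421049807305645	0.04488721401043664	d28_vs_control
gene_0013	-0.6259521858123582	0.16998695164531377	0.17581827496184824	d28_vs_control
gene_0014	-1.2997339422506045	0.009725215557143077	0.022442805131868637	d28_vs_control
gene_0015	-1.0163038134112217	0.06781391773263426	0.07680073080059814	d28_vs_control
gene_0016	-0.7822067773267456	0.08941032063002312	0.0957967721035962	d28_vs_control
gene_0017	1.257369399331738	0.023571132041301377	0.037217576907317966	d28_vs_control
gene_0018	1.2647427949255894	0.003042203218227744	0.01140826206835404	d28_vs_control
gene_0019	1.0769331186075286	0.013286341460646837	0.028215180072222523	d28_vs_control
gene_0020	1.3934079328157996	0.049418949335421694	0.06445949913315872	d28_vs_control
gene_0021	1.0776347973917666	0.022010096488424884	0.037217576907317966	d28_vs_control
gene_0022	1.807256386619719	0.05645774465392995	0.06774929358471593	d28_vs_control
gene_0023	0.8178823701663465	0.17581827496184824	0.17581827496184824	d28_vs_control
gene_0024	1.118639804297053	0.0020071613189863355	0.01140826206835404	d28_vs_control
gene_0025	-1.3439133316865064	0.0009720475161644018	0.009720475161644017	d28_vs_control
gene_0026	-1.0350786463562782	0.05424722601943861	0.06774929358471593	d28_vs_control
gene_0027	-1.1574374752255254	0.023568122282467584	0.037217576907317966	d28_vs_control
gene_0028	-1.1680284396200733	0.06912065772053833	0.07680073080059814	d28_vs_control
gene_0029	-1.1966398409211383	0.0017383121792451071	0.01140826206835404	d28_vs_control
gene_0030	-1.0403808028064532	0.003849176814304612	0.012830589381015374	d28_vs_control
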