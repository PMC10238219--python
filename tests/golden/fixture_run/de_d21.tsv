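feature	log2fc	pvalue	padj	contrast
gene_0001	-3.288813992628445	0.016731828502421456	0.029526756180743748	d21_vs_control
gene_0002	-2.8950687662327734	0.0005900703272638707	0.004086863920162706	d21_vs_control
gene_0003	-2.9106586197402633	0.0011533684105414163	0.0049430074737489265	d21_vs_control
gene_0004	-2.627688710517126	0.00718169475298959	0.017954236882473974	d21_vs_control
gene_0005	-3.3217255922185247	0.0006334320878364995	0.004086863920162706	d21_vs_control
gene_0006	-2.9330790592589455	9.15013997278724e-05	0.002202539475921971	d21_vs_control
gene_0007	-3.132539754449014	0.00014683596506146474	0.002202539475921971	d21_vs_control
gene_0008	-3.3760081466393648	0.012884015930487653	0.025802498593191774	d21_vs_control
gene_0009	0.4445769039834282	0.030859080751989006	0.049733762326450756	d21_vs_control
gene_0010	-0.0914300528546903	0.7949098865449504	0.8223205722878797	d21_vs_control
gene_0011	0.3291467757569446	0.2987801918792478	0.34474637524528595	d21_vs_control
gene_0012	0.09564354122572283	0.7542832432338805	0.8081606177505862	d21_vs_control
gene_0013	0.3633262603220331	0.062247486023589337	0.08119237307424695	d21_vs_control
gene_0014	0.033323475187550855	0.877211249933367	0.877211249933367	d21_vs_control
gene_0015	0.14851242344969506	0.6080089836614074	0.6755655374015638	d21_vs_control
gene_0016	0.646072434138306	0.04740080263618412	0.06771543233740589	d21_vs_control
gene_0017	1.377794020933921	0.003740976593318446	0.01122292977995534	d21_vs_control
gene_0018	1.5438644020553562	0.0006811439866937843	0.004086863920162706	d21_vs_control
gene_0019	1.5768926875934053	0.012901249296595887	0.025802498593191774	d21_vs_control
gene_0020	1.0359493316591282	0.10317501298942051	0.12381001558730462	d21_vs_control
gene_0021	0.9108562457423179	0.05037548829141248	0.06869384767010793	d21_vs_control
gene_0022	2.1954582350865453	0.03149804947341881	0.049733762326450756	d21_vs_control
gene_0023	1.2458776190013214	0.0029931461089352037	0.01122292977995534	d21_vs_control
gene_0024	1.2341728778470875	0.0037280387913263325	0.01122292977995534	d21_vs_control
gene_0025	-1.6466318867901517	0.0009791363593607098	0.004895681796803549	d21_vs_control
gene_0026	-0.730108494525509	0.0960522627486316	0.1200653284357895	d21_vs_control
gene_0027	-0.9140198549568188	0.04259414868639483	0.06389122302959224	d21_vs_control
gene_0028	-1.217597601130052	0.014268972043417143	0.02675432258140714	d21_vs_control
gene_0029	-1.1593077511998375	0.007853880342754879	0.018124339252511258	d21_vs_control
gene_0030	-1.0098775552014132	0.004226443971033984	0.01152666537554723	d21_vs_control
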