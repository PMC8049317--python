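id	PROT0001	PROT0002	PROT0003	PROT0004	PROT0005	PROT0006	PROT0007	PROT0008
S0001	14.662907962451982	13.647192868551823				13.24512745385457		
S0002	15.75177972035077	12.398404840802995	15.959056805194257	14.96798916297231				13.74412987436684
S0003	15.516367550107034		17.2677301329704	15.047163741620208	13.269790001627726			14.018151426125906
S0004	14.843570640257843		16.884533398558986	13.046763072117935			16.450100992083648	14.518462811685959
S0005	15.430680958858394		17.670204282708685		13.110583611456848	12.036175000830013	16.904103043689048	
S0006	15.060477880389948	10.809010738354102	14.36222617872876	12.75626930348026	13.320237682986436		18.27745532355182	
S0007	16.764867212048966		14.82792015240619		13.31328059245896		15.991741067385034	14.311645570633337
S0008	15.869454888121162		15.345824779370005	12.39753726852511	11.77606565808367			14.829256248325683
S0009		12.903610399636776	17.112704123568403	14.267117554230511	13.058294757184164		19.555585470726353	14.283738476717659
S0010	16.18997672871091	10.77927921250193					15.295376269149976	13.356359797175639
S0011	14.740803589943413		15.618787715753502	15.054851047014315	15.734697246947453		17.620975455868574	
S0012			15.690005953705272	15.15376704614782	14.58953878408564	14.101709826655735	16.655050664337235	
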