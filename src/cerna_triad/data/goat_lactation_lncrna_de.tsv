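feature_id	foldChange	log2FoldChange	pval	up_down	gene_id	class_code
TCONS_00003699	Inf	Inf	0.004706517	Up	XLOC_002888	u
TCONS_00055666	Inf	Inf	0.010807149	Up	XLOC_042144	u
TCONS_00066337	Inf	Inf	0.033426028	Up	XLOC_050454	u
TCONS_00080513	Inf	Inf	0.030710818	Up	XLOC_061087	u
TCONS_00148053	Inf	Inf	0.002143822	Up	XLOC_110768	u
TCONS_00148514	76.19620987	6.251647332	0.003516268	Up	XLOC_111117	u
TCONS_00063833	68.69470734	6.102127044	0.029434776	Up	XLOC_048464	o
TCONS_00143844	52.60107296	5.717020323	0.001761151	Up	XLOC_107655	u
TCONS_00158176	48.33903097	5.595116647	2.27E-05	Up	XLOC_118081	u
TCONS_00129994	32.29835189	5.013388644	0.015843692	Up	XLOC_097220	u
TCONS_00067523	31.87609402	4.994402952	0.032826209	Up	XLOC_051367	u
TCONS_00062140	17.92388624	4.16381157	0.011608389	Up	XLOC_047101	u
TCONS_00011031	11.4250959	3.51413437	0.01663844	Up	XLOC_008649	u
TCONS_00144689	11.38306796	3.50881754	0.000908273	Up	XLOC_108139	u
TCONS_00088402	7.928516015	2.987050861	0.003135758	Up	XLOC_067279	u
TCONS_00061579	7.079741575	2.8236967	0.001287427	Up	XLOC_046679	u
TCONS_00041067	6.941202278	2.795185572	0.023619753	Up	XLOC_031274	u
TCONS_00102108	6.93225827	2.793325405	0.020870614	Up	XLOC_077600	u
TCONS_00108242	6.807163735	2.767053812	0.039646296	Up	XLOC_082113	u
TCONS_00081414	6.661186743	2.735779228	0.028152774	Up	XLOC_061778	o
TCONS_00138804	5.600968309	2.485676265	0.03168414	Up	XLOC_103830	u
TCONS_00111220	5.349384894	2.419373011	0.044515453	Up	XLOC_084271	u
TCONS_00091259	5.185906859	2.374596295	0.010227508	Up	XLOC_069374	u
TCONS_00128617	4.959484256	2.310190101	0.00530008	Up	XLOC_096084	u
TCONS_00144434	4.107474541	2.038251633	0.010156005	Up	XLOC_107993	u
TCONS_00111216	4.088620971	2.031614326	0.038218475	Up	XLOC_084271	u
TCONS_00001644	3.736372488	1.901638288	0.01127339	Up	XLOC_001306	u
TCONS_00110456	3.725766119	1.897537114	0.01108338	Up	XLOC_083717	u
TCONS_00091228	0.094906909	-3.39734307	0.049702596	Down	XLOC_069347	i
TCONS_00146083	0.073915782	-3.75797377	0.001717991	Down	XLOC_109192	u
TCONS_00055279	0.051221771	-4.28709905	0.015184126	Down	XLOC_041859	u
TCONS_00122260	0	0	0.004657073	Down	XLOC_091603	o
TCONS_00132241	0	0	0.009949405	Down	XLOC_098926	u
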