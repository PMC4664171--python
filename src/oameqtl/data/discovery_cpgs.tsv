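snp_id	cpg_id	chromosome	position	adj_p_all	adj_p_oa	direction_vs_risk	nearest_gene
rs6976	cg18099408	3	52552593	3.19e-8	3.73e-6	lower	STAB1
rs6976	cg15147215	3	52552868	0.005	0.04	lower	STAB1
rs6976	cg18591801	3	52553433	0.004	0.04	lower	STAB1
rs10948172	cg13979708	6	44695318	9.83e-6	6.2e-5	lower	SUPT3H
rs10948172	cg19254793	6	44695348	0.008	0.009	lower	SUPT3H
rs10948172	cg20913747	6	44695427	8.75e-13	4.9e-12	lower	SUPT3H
rs10948172	cg18551225	6	44695536	1.70e-10	1.12e-10	lower	SUPT3H
rs3204689	cg12031962	15	58353849	1.03e-10	2.0e-8	lower	ALDH1A2
rs143383	cg14752227	20	34000481	0.001	0.01	lower	UQCC
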