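Gene	Subset	Tier_Group	Cancer_AF	Control_AF	Cancer_Alt_Count	Cancer_Total_Count	Control_Alt_Count	Control_Total_Count	p_greater	OR_cmle	FDR_greater	p_twosided	FDR_twosided	stats_reliable
RPA1	PanCancer_UltraRare	ULTRA_RARE_PLUS_NOVEL	0.0029	0.0017	35	11951	466	267908	0.00350858	1.6837	0.028068639	0.00531368	0.042509437	1
RPA1	HEM_UltraRare	ULTRA_RARE_PLUS_NOVEL	0.0022	0.0017	15	6889	466	267908	0.231331347	1.2518	0.462662694	0.37871645	0.504955267	1
RPA1	ST_UltraRare	ULTRA_RARE_PLUS_NOVEL	0.0033	0.0017	13	3935	466	267908	0.024524772	1.8993	0.09809909	0.031863803	0.127455213	1
RPA1	CNS_UltraRare	ULTRA_RARE_PLUS_NOVEL	0.0033	0.0017	7	2129	466	267908	0.083930393	1.8903	0.223814382	0.107377392	0.214754784	1
RPA2	PanCancer_UltraRare	ULTRA_RARE_PLUS_NOVEL	0.0006	0.0007	7	11979	200	268174	0.785228312	NA	NA	NA	NA	0
RPA3	PanCancer_UltraRare	ULTRA_RARE_PLUS_NOVEL	0.0008	0.0006	9	11977	164	268210	0.32195265	NA	NA	NA	NA	0
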