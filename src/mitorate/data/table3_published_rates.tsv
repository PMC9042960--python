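# Published mtDNA mutation rates for comparison, with the counts and unit
# conventions needed to standardise them to mutations/site/Myr at a 25-year
# generation.  Rows labelled *_current are this pipeline's own estimates
# (counts from the bundled lineage fixture, reported value at a 26.9-year
# generation).  Where a study's raw counts are given, standardisation
# recomputes the rate from the counts; otherwise the reported value is
# converted.  standardized_printed is the value as printed in the comparison
# table of the source study (not always reproducible from the data given;
# such rows are retained for completeness).
study	region	type	seq_range	transmissions	n_sub	n_het	reported_value	reported_units	generation_years	standardized_printed
hvi_ped_a	HVI	pedigree	16024-16383	321			1.84e-6	per_site_per_generation		0.074
hvi_phylo_a	HVI	phylogenetic	16024-16401				10.3e-8	per_site_per_year		0.103
hvi_ped_b	HVI	pedigree	L15997-H202	920			0.45	per_site_per_Myr	20	0.360
hvi_ped_c	HVI	pedigree	16024-16383	705	3	3				0.948
hvi_current	HVI	pedigree	16024-16383	345	1	3	1.201	per_site_per_Myr	26.9	1.292
hvi_ped_d	HVI	pedigree	16024-16383	321	0	6				2.083
hvi_ped_e	HVI	pedigree	16024-16383	299			1.1e-6	per_site_per_generation		2.844
hvii_phylo_a	HVII	phylogenetic	29-408				7.39e-8	per_site_per_year		0.074
hvii_ped_a	HVII	pedigree	57-371	705	1	0				0.181
hvii_ped_b	HVII	pedigree	L16483-H580	910			0.42	per_site_per_Myr	20	0.336
hvii_current	HVII	pedigree	57-371	345	0	1	0.343	per_site_per_Myr	26.9	0.369
hvii_ped_c	HVII	pedigree	57-371	321			0.83e-6	per_site_per_generation		0.433
hvii_ped_d	HVII	pedigree	57-371	321	0	5				1.984
hvihvii_ped_a	HVI_HVII	pedigree	L16483-H580	910			0.21	per_site_per_Myr	20	0.168
hvihvii_ped_b	HVI_HVII	pedigree	57-371,16024-16383	321			6.04e-6	per_site_per_generation		0.241
hvihvii_ped_c	HVI_HVII	pedigree	57-371,16024-16383	705			0.32	per_site_per_Myr	20	0.256
hvihvii_adna_a	HVI_HVII	aDNA	undefined				31.43e-8	per_site_per_year		0.314
hvihvii_ped_d	HVI_HVII	pedigree	57-371,16024-16383	705	3	3				0.506
hvihvii_current	HVI_HVII	pedigree	57-371,16024-16383	345	1	4	0.801	per_site_per_Myr	26.9	0.861
hvihvii_ped_e	HVI_HVII	pedigree	undefined	327			2.5	per_site_per_Myr	20	2.000
hvihvii_ped_f	HVI_HVII	pedigree	57-371,16024-16383	321	0	11				2.037
ctrl_ped_a	control	pedigree	undefined				1.5e-6	per_site_per_generation		0.060
ctrl_phylo_a	control	phylogenetic	undefined				7.00e-8	per_site_per_year		0.070
ctrl_ped_b	control	pedigree	1-400,16024-16569	321			4.19e-6	per_site_per_generation		0.168
ctrl_ped_c	control	pedigree	L15997-H202,L16483-H580	920			0.21	per_site_per_Myr	20	0.168
ctrl_ped_d	control	pedigree	1-576,16024-16569	185	1	0				0.188
ctrl_current	control	pedigree	1-576,16024-16569	345	1	4	0.469	per_site_per_Myr	26.9	0.505
ctrl_ped_e	control	pedigree	1-400,16024-16569	321			1.28e-5	per_site_per_generation		0.512
ctrl_ped_f	control	pedigree	1-400,16024-16569	321			1.92e-5	per_site_per_generation		0.768
ctrl_ped_g	control	pedigree	1-400,16024-16569	321	0	11				1.194
cod_adna_a	coding	aDNA	577-16023				1.25e-8	per_site_per_year		0.0125
cod_phylo_a	coding	phylogenetic	undefined				1.70e-8	per_site_per_year		0.017
cod_ped_a	coding	pedigree	3230-4331	311			5.89e-7	per_site_per_generation		0.024
cod_current	coding	pedigree	577-16023	345	1	3	0.028	per_site_per_Myr	26.9	0.030
cod_ped_b	coding	pedigree	3230-4331	311			1.03e-6	per_site_per_generation		0.041
cod_ped_c	coding	pedigree	3230-4331	311			5.84e-6	per_site_per_generation		0.234
cod_ped_d	coding	pedigree	3230-4331	311			5.84e-6	per_site_per_generation		0.234
cod_ped_e	coding	pedigree	3230-4331	311			8.75e-6	per_site_per_generation		0.350
cod_ped_f	coding	pedigree	3230-4331	311			8.75e-6	per_site_per_generation		0.350
cod_ped_g	coding	pedigree	5550-6550	2560			0.54	per_site_per_Myr	20	0.432
mt_ped_a	mtGenome	pedigree	1-16569				2.7e-7	per_site_per_generation		0.011
mt_adna_a	mtGenome	aDNA	undefined				1.92e-8	per_site_per_year		0.019
mt_adna_b	mtGenome	aDNA	undefined				2.143e-8	per_site_per_year		0.021
mt_adna_c	mtGenome	aDNA	undefined				2.4e-8	per_site_per_year		0.024
mt_current	mtGenome	pedigree	1-16569	345	2	7	0.058	per_site_per_Myr	26.9	0.063
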