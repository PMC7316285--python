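symbol	chromosome	start	end	evidence_type	evidence_id	distance	trait_code
EEPD1	4	61354648	61476979	qtl	20355	0.6	CW
EEPD1	4	61354648	61476979	qtl	20368	0.6	FT12R
EEPD1	4	61354648	61476979	snp	Hapmap42645-BTA-70875	1.84	CC
MYH10	19	28680825	28800880	qtl	22873	-22.3	IMF
MYH10	19	28680825	28800880	qtl	22872	-2.6	IMF
MYH10	19	28680825	28800880	snp	UA-IFASA-9813	3.92	CW
MYH10	19	28680825	28800880	snp	ARS-BFGL-NGS-88422	0.82	CC
CYP2R1	15	38420926	38445583	qtl	24706	-6.7	LDMA
CYP2R1	15	38420926	38445583	snp	ARS-BFGL-NGS-117790	2.12	CC
GADL1	22	5258463	5452369	qtl	37164	-2.0	LMY
GADL1	22	5258463	5452369	snp	ARS-BFGL-NGS-27027	0.06	CC
MYH1	19	30110728	30134757	qtl	22873	-19.9	IMF
MYH1	19	30110728	30134757	snp	UA-IFASA-9813	2.58	CW
MYH1	19	30110728	30134757	snp	ARS-BFGL-NGS-88422	2.25	CC
SHISA3	6	62877287	62880849	qtl	20764	-0.8	SF
SHISA3	6	62877287	62880849	snp	BTA-76543-no-rs	1.13	IMFP
MYH4	19	30080604	30103436	qtl	22873	-19.9	IMF
MYH4	19	30080604	30103436	snp	UA-IFASA-9813	2.61	CW
MYH4	19	30080604	30103436	snp	ARS-BFGL-NGS-88422	2.22	CC
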