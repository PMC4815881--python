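snp_id	gene	band	risk_allele_freq	per_allele_or
# 12q21 carries a second, independently associated SNP (rs1508595, freq 0.83, OR 2.69);
# only the primary signal rs995030 enters the risk-score model.
rs995030	KITLG	12q21	0.80	2.55
rs210138	BAK1	6p21	0.20	1.50
rs4624820	SPRY4	5q31	0.54	1.37
rs4635969	TERT/CLPTM1L	5p15	0.20	1.54
rs755383	DMRT1	9p24	0.62	1.37
rs2900333	ATF7IP	12p13	0.62	1.27
rs8046148	HEATR3	16q12.1	0.79	1.32
rs2839243	non-coding	21q22.3	0.47	1.26
rs3805663	CATSPER3/PITX1	5q31.1	0.63	1.25
rs10510452	DAZL	3p24.3	0.70	1.24
rs2720460	CENPE	4q24	0.62	1.24
rs7010162	PRDM14	8q13.3	0.62	1.22
rs9905704	RAD51C/TEX14/PPM1E	17q22	0.68	1.21
rs3790672	non-coding	1q24.1	0.28	1.20
rs2072499	non-coding	1q22	0.35	1.19
rs4888262	RFWD3	16q22.3	0.458	1.21
rs12699477	MAD1L1	7p22.3	0.38	1.16
rs17021463	HPGDS	4q22.2	0.42	1.15
rs1510272	SSR3/TIPARP	3q25	0.73	1.16
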