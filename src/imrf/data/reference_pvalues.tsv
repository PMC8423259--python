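comparison	rank	gene	pvalue
late_ad_vs_pure_late	1	HS.406790	1.02E-4
late_ad_vs_pure_late	2	NDUFA7	7.91E-5
late_ad_vs_pure_late	3	HS.253475	1.31E-3
late_ad_vs_pure_late	4	DDX26B	5.20E-2
late_ad_vs_pure_late	5	MANBAL	8.84E-1
late_ad_vs_pure_late	6	C8ORF58	3.62E-4
late_ad_vs_pure_late	7	OVOS2	9.51E-1
late_ad_vs_pure_late	8	ZBTB5	9.75E-5
late_ad_vs_pure_late	9	VGF	7.67E-5
late_ad_vs_pure_late	10	HS.559151	1.07E-2
late_ad_vs_pure_late	11	HS.561747	1.29E-4
late_ad_vs_pure_late	12	KEAP1	6.66E-4
late_ad_vs_pure_late	13	HS.554346	2.97E-3
late_ad_vs_pure_late	14	STARD7	1.67E-4
late_ad_vs_pure_late	15	LOC651123	4.38E-3
late_ad_vs_pure_late	16	UIMC1	7.26E-2
late_ad_vs_pure_late	17	SEC31B	2.91E-2
late_ad_vs_pure_late	18	HS.128396	1.34E-3
late_ad_vs_pure_late	19	LOC441546	7.62E-4
late_ad_vs_pure_late	20	LOC391692	7.48E-5
late_ad_vs_pure_ad	1	RNASE4	8.83E-1
late_ad_vs_pure_ad	2	OSR2	2.72E-3
late_ad_vs_pure_ad	3	EPGN	1.57E-4
late_ad_vs_pure_ad	4	CDC6	2.18E-4
late_ad_vs_pure_ad	5	SP140	1.26E-1
late_ad_vs_pure_ad	6	ADSSL1	5.21E-1
late_ad_vs_pure_ad	7	OVOS2	2.71E-1
late_ad_vs_pure_ad	8	LOC645723	4.38E-3
late_ad_vs_pure_ad	9	CLEC7A	7.17E-1
late_ad_vs_pure_ad	10	HS.543051	7.59E-4
late_ad_vs_pure_ad	11	HS.560742	3.80E-5
late_ad_vs_pure_ad	12	IL29	2.89E-1
late_ad_vs_pure_ad	13	LOC648251	3.82E-3
late_ad_vs_pure_ad	14	TNR	1.69E-3
late_ad_vs_pure_ad	15	TPSG1	4.73E-2
late_ad_vs_pure_ad	16	FGF16	1.46E-3
late_ad_vs_pure_ad	17	HS.416810	1.48E-2
late_ad_vs_pure_ad	18	HS.135067	8.17E-3
late_ad_vs_pure_ad	19	FBXO43	2.00E-3
late_ad_vs_pure_ad	20	HS.536734	4.25E-3
late_ad_vs_pure_ad	21	HS.156651	3.78E-5
late_ad_vs_pure_ad	22	PLA2G15	2.21E-3
late_ad_vs_pure_ad	23	FLJ42133	3.36E-4
late_ad_vs_pure_ad	24	BARX2	1.22E-3
pure_late_vs_pure_ad	1	ANAPC11	6.91E-2
pure_late_vs_pure_ad	2	SGCD	4.85E-1
pure_late_vs_pure_ad	3	CDC6	4.69E-4
pure_late_vs_pure_ad	4	HYOU1	5.56E-4
pure_late_vs_pure_ad	5	GRIPAP1	4.51E-2
pure_late_vs_pure_ad	6	DTNB	4.33E-2
pure_late_vs_pure_ad	7	NIPBL	5.00E-1
pure_late_vs_pure_ad	8	SLTM	2.59E-4
pure_late_vs_pure_ad	9	XKRY	3.50E-3
pure_late_vs_pure_ad	10	ZHX1	5.37E-3
pure_late_vs_pure_ad	11	SEC14L5	7.27E-4
pure_late_vs_pure_ad	12	CLEC7A	7.79E-1
pure_late_vs_pure_ad	13	GOLGA4	2.33E-3
pure_late_vs_pure_ad	14	PSMB8	9.93E-1
pure_late_vs_pure_ad	15	USP4	7.95E-1
pure_late_vs_pure_ad	16	ZNF823	2.24E-3
pure_late_vs_pure_ad	17	FBXO43	1.18E-4
pure_late_vs_pure_ad	18	SRPR	4.05E-5
pure_late_vs_pure_ad	19	HS.581994	1.14E-3
pure_late_vs_pure_ad	20	INHA	1.20E-2
pure_late_vs_pure_ad	21	BHLHB9	8.37E-2
late_ad_vs_control	1	NDUFA7	2.75E-7
late_ad_vs_control	2	LOC644291	6.02E-4
late_ad_vs_control	3	DDIT3	6.68E-3
late_ad_vs_control	4	LOC730534	5.31E-6
late_ad_vs_control	5	MED25	1.52E-5
late_ad_vs_control	6	HSP90B1	3.97E-5
late_ad_vs_control	7	NSMCE1	7.01E-5
late_ad_vs_control	8	LOC148915	2.59E-7
late_ad_vs_control	9	SDSL	5.72E-4
late_ad_vs_control	10	NRIP2	1.28E-6
late_ad_vs_control	11	SMAD7	5.75E-1
late_ad_vs_control	12	SLC6A12	5.39E-7
pure_late_vs_control	1	SEC31B	3.46E-3
pure_late_vs_control	2	LOC392481	7.24E-5
pure_late_vs_control	3	NEUROG1	8.55E-5
pure_late_vs_control	4	N-PAC	3.83E-5
pure_late_vs_control	5	HS.540598	7.54E-5
pure_late_vs_control	6	SGCD	7.38E-1
pure_late_vs_control	7	HS.543684	9.86E-5
pure_late_vs_control	8	HS.542777	6.39E-5
pure_late_vs_control	9	C2ORF61	9.00E-4
pure_late_vs_control	10	HS.545899	4.10E-3
pure_late_vs_control	11	RBM4	1.99E-1
pure_late_vs_control	12	LOC150207	1.59E-4
pure_late_vs_control	13	AHCTF1	5.51E-2
pure_late_vs_control	14	ARF1	7.62E-3
pure_late_vs_control	15	HS.579437	3.48E-3
pure_late_vs_control	16	TMSB4X	4.15E-4
pure_late_vs_control	17	HS.549460	2.55E-3
pure_late_vs_control	18	HSFY1	1.80E-3
pure_ad_vs_control	1	ALG9	8.66E-5
pure_ad_vs_control	2	CDC6	4.38E-4
pure_ad_vs_control	3	C11ORF17	3.10E-1
pure_ad_vs_control	4	LOC392395	6.34E-4
pure_ad_vs_control	5	JUB	4.58E-1
pure_ad_vs_control	6	ALAD	3.04E-4
pure_ad_vs_control	7	HS.581468	4.22E-3
pure_ad_vs_control	8	HS.543116	5.71E-3
pure_ad_vs_control	9	LOC651208	7.81E-3
pure_ad_vs_control	10	CLEC7A	7.69E-1
pure_ad_vs_control	11	LOC440934	2.59E-3
pure_ad_vs_control	12	LOC728056	3.06E-4
pure_ad_vs_control	13	SEPHS1	1.86E-3
pure_ad_vs_control	14	INHA	2.94E-2
four_class	1	LOC391692	1.09E-6
four_class	2	NEUROG1	9.79E-4
four_class	3	STARD7	6.84E-5
four_class	4	LOC148915	2.47E-7
four_class	5	CLEC7A	7.12E-1
four_class	6	SEC31B	2.83E-2
four_class	7	MED25	5.37E-6
four_class	8	SGCD	6.74E-1
four_class	9	N-PAC	2.34E-4
four_class	10	KPTN	3.72E-5
four_class	11	HS.529514	4.86E-6
four_class	12	LOC392481	3.69E-4
four_class	13	LOC441546	7.00E-4
four_class	14	MANBAL	1.78E-1
four_class	15	HS.542777	7.76E-5
four_class	16	LOC730534	8.67E-6
four_class	17	NDUFA7	8.32E-7
four_class	18	C2ORF61	2.82E-3
four_class	19	HS.540598	1.58E-3
four_class	20	KEAP1	1.42E-3
four_class	21	LOC440934	2.65E-4
four_class	22	TRMT5	7.21E-6
four_class	23	ARMCX6	1.38E-1
four_class	24	BRD4	9.90E-1
four_class	25	HS.406790	7.50E-4
four_class	26	PCDH12	6.00E-2
four_class	27	NSMCE1	2.56E-4
four_class	28	LOC651123	5.53E-2
four_class	29	SLTM	9.12E-5
four_class	30	ZBTB5	2.57E-3
four_class	31	HSFY1	1.29E-2
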