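# Per-locus QTL evidence at the 39 suggestive sepsis GWAS loci (three studies).
# One row per (lead SNP, phenotype) pair; qtl_type "none" marks leads with no
# catalogued eQTL or cytokine-QTL hit. P-values transcribed with dot decimals.
study	lead_snp	qtl_type	phenotype	pvalue
Rautanen A	rs2709532	none	No
Rautanen A	rs72661895	none	No
Rautanen A	rs4957796	none	No
Rautanen A	rs79423885	none	No
Rautanen A	rs76881522	none	No
Rautanen A	rs12114790	eqtl	CSGALNACT1	9.50E-66
Rautanen A	rs12114790	eqtl	INTS10	3.27E-09
Rautanen A	rs12114790	cytokine	IL1b_C.albicansconidia_PBMC_24h	0.010228723
Rautanen A	rs12114790	cytokine	IL6_C.albicanshyphae_PBMC_24h	0.026800224
Rautanen A	rs12114790	cytokine	TNFA_C.albicansconidia_PBMC_24h	0.040662939
Rautanen A	rs9566343	cytokine	IL22_C.albicansconidia_PBMC_7days	0.009406105
Rautanen A	rs9566343	cytokine	IL6_LPS100ng_PBMC_24h	0.022034182
Rautanen A	rs6501341	none	No
Rautanen A	rs2096460	eqtl	URB1	6.89E-152
Rautanen A	rs2096460	eqtl	C21orf119	1.57E-21
Scherag A	rs382422	eqtl	WLS	8.66E-12
Scherag A	rs382422	cytokine	IFNy_C.albicansconidia_PBMC_7days	0.006355623
Scherag A	rs150811371	none	No
Scherag A	rs945177	none	No
Scherag A	rs9529561	none	No
Scherag A	rs2641697	eqtl	CRISPLD2	1.18E-08
Scherag A	rs2641697	eqtl	KIAA0513	6.31E-07
Scherag A	rs2641697	cytokine	IL6_S.aureus_PBMC_24h	0.029215619
Scherag A	rs7211184	none	No
Scherag A	rs58764888	none	No
Scherag A	rs72862231	none	No
Scherag A	rs150062338	none	No
Scherag A	rs10933728	none	No
Scherag A	rs115550031	eqtl	DGKQ	5.95E-06
Scherag A	rs62369989	cytokine	IL17_C.albicansconidia_PBMC_7days	0.011402725
Scherag A	rs117983287	none	No
Scherag A	rs409443	none	No
Srinivasan L	rs3100127	eqtl	PTPN7	3.48E-91
Srinivasan L	rs3100127	eqtl	LGR6	6.01E-16
Srinivasan L	rs41461846	eqtl	CYP27A1	3.2717E-310
Srinivasan L	rs41461846	eqtl	RQCD1	3.2717E-310
Srinivasan L	rs41461846	eqtl	VIL1	4.3769E-101
Srinivasan L	rs41461846	eqtl	TTLL4	1.3023E-79
Srinivasan L	rs41461846	eqtl	STK36	9.0469E-76
Srinivasan L	rs41461846	eqtl	USP37	4.9084E-71
Srinivasan L	rs41461846	eqtl	SLC11A1	3.4111E-61
Srinivasan L	rs41461846	eqtl	ZNF142	2.6409E-55
Srinivasan L	rs41461846	eqtl	PRKAG3	6.0805E-38
Srinivasan L	rs41461846	eqtl	BCS1L	1.8409E-37
Srinivasan L	rs72998754	none	No
Srinivasan L	rs3844280	eqtl	BRK1	1.83E-180
Srinivasan L	rs3844280	eqtl	LINC00852	6.43E-19
Srinivasan L	rs3844280	eqtl	FANCD2	8.65E-12
Srinivasan L	rs3844280	eqtl	IRAK2	6.97E-11
Srinivasan L	rs3844280	eqtl	CRELD1	5.51E-06
Srinivasan L	rs12490944	eqtl	RBM6	2.01E-195
Srinivasan L	rs12490944	eqtl	HYAL3	2.98E-98
Srinivasan L	rs12490944	eqtl	MON1A	1.56E-79
Srinivasan L	rs12490944	eqtl	UBA7	5.21E-59
Srinivasan L	rs12490944	eqtl	APEH	5.64E-27
Srinivasan L	rs12490944	eqtl	AMT	3.54E-21
Srinivasan L	rs12490944	eqtl	NICN1	2.61E-20
Srinivasan L	rs12490944	eqtl	IFRD2	4.12E-10
Srinivasan L	rs12490944	eqtl	NAT6	2.39E-08
Srinivasan L	rs12490944	eqtl	KLHDC8B	4.60E-08
Srinivasan L	rs12490944	eqtl	QRICH1	2.34E-07
Srinivasan L	rs12490944	eqtl	TCTA	1.42E-05
Srinivasan L	rs12490944	eqtl	MST1	1.57E-05
Srinivasan L	rs12490944	eqtl	FAM212A	1.74E-05
Srinivasan L	rs17599816	none	No
Srinivasan L	rs6462728	eqtl	AOAH	1.65E-26
Srinivasan L	rs6462728	cytokine	IL17_C.albicansconidia_PBMC_7days	0.010838542
Srinivasan L	rs6462728	cytokine	IL6_C.albicansconidia_PBMC_24h	0.020869368
Srinivasan L	rs2237499	eqtl	LINC00265	4.59E-91
Srinivasan L	rs2237499	eqtl	RALA	5.32E-18
Srinivasan L	rs2237499	eqtl	CDK13	7.48E-14
Srinivasan L	rs2237499	cytokine	IL1b_LPS100ng_PBMC_24h	0.000626831
Srinivasan L	rs2237499	cytokine	TNFA_C.albicansconidia_PBMC_24h	0.012141737
Srinivasan L	rs2237499	cytokine	IL6_LPS100ng_PBMC_24h	0.017978737
Srinivasan L	rs2237499	cytokine	IL1b_E.Coli_PBMC_24h	0.033518435
Srinivasan L	rs4730486	eqtl	IMMP2L	3.2717E-310
Srinivasan L	rs513793	none	No
Srinivasan L	rs11597285	none	No
Srinivasan L	rs74487835	none	No
Srinivasan L	rs16913666	none	No
Srinivasan L	rs11840143	cytokine	IL22_C.albicansconidia_PBMC_7days	0.021643788
Srinivasan L	rs11840143	cytokine	IFNy_C.albicansconidia_PBMC_7days	0.049325944
Srinivasan L	rs13380717	cytokine	IFNy_C.albicanshyphae_PBMC_7days	2.51E-06
Srinivasan L	rs13380717	cytokine	IL22_C.albicanshyphae_PBMC_7days	0.003182544
Srinivasan L	rs13380717	cytokine	TNFA_E.Coli_PBMC_24h	0.032629607
Srinivasan L	rs13380717	cytokine	IL1b_E.Coli_PBMC_24h	0.043946978
Srinivasan L	rs645505	eqtl	NAPG	5.33E-06
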