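rsid	gene	locus	or	risk_allele	chrom_class
rs12080929	TRABD2B	1p33	0.87	C	autosomal
rs6687758	DUSP10	1q41	1.04	G	autosomal
rs6691170	LOC105372950/DUSP10	1q41	1.01	T	autosomal
rs10911251	LAMC1	1q25.3	1.11	A	autosomal
rs11903757	NABP1/SDPR	2q32.3	1.14	C	autosomal
rs10936599	MYNN	3q26.2	1.02	C	autosomal
rs647161	C5orf66	5q31.1	1.07	A	autosomal
rs2736100	TERT	5p15.33	1.07	A	autosomal
rs1321311	SRSF3/CDKN1A	6p21.2	1.07	A	autosomal
rs11987193	DUSP4	8p12	0.79	T	autosomal
rs16892766	TRPS1/EIF3H/UTP23	8q23.3	1.25	C	autosomal
rs6983267	CCAT2	8q24.21	1.15	G	autosomal
rs10505477	CASC8	8q24.21	1.11	A	autosomal
rs7014346	CASC8/POU5F1B	8q24.21	1.20	A	autosomal
rs719725	TPD52L3/UHRF2/GLDC	9p24.1	1.08	A	autosomal
rs10795668	LOC105376400	10p14	1.32	A	autosomal
rs704017	ZMIZ1-AS1	10q22.3	1.13	G	autosomal
rs1035209	ABCC2/MRP2	10q24.2	1.13	T	autosomal
rs12241008	VTI1A	10q25.2	1.19	C	autosomal
rs11196172	TCF7L2	10q25.2	1.14	A	autosomal
rs1665650	HSPA12A	10q25.3	0.95	T	autosomal
rs174537	TNEM258/MYRF	11q12.2	1.16	G	autosomal
rs4246215	TNEM258/FEN1	11q12.2	1.15	G	autosomal
rs174550	FADS1	11q12.2	1.15	T	autosomal
rs1535	FADS2/FADS1	11q12.2	1.15	A	autosomal
rs3802842	COLCA1/COLCA2	11q23.1	1.14	C	autosomal
rs10849432	LOC105369625	12p13.31	1.14	T	autosomal
rs3217810	CCND2/CCND2-AS1	12p13.32	1.19	T	autosomal
rs3217901	CCND2	12p13.32	1.10	G	autosomal
rs10774214	CCND2	12p13.32	1.17	T	autosomal
rs7136702	LARP4/DIP2B/ATF1	12q13.12	1.10	T	autosomal
rs11169552	LARP4/DIP2B/ATF1	12q13.12	1.05	C	autosomal
rs59336	TBX3	12q24.21	1.15	T	autosomal
rs4444235	BMP4/ATP5C1P1/CDKN3/MIR5580	14q22.2	1.11	C	autosomal
rs1957636	LOC105370507	14q22.2	1.03	T	autosomal
rs4779584	SCG5/GREM1/FMN1	15q13.3	1.18	T	autosomal
rs16969681	GREM1	15q13.3	1.18	T	autosomal
rs11632715	SCG5/GREM1/FMN1	15q13.3	1.12	A	autosomal
rs9929218	CDH1	16q22.1	1.10	A	autosomal
rs12603526	NXN	17p13.3	1.10	C	autosomal
rs4939827	SMAD7	18q21.1	1.16	T	autosomal
rs10411210	RHPN2	19q13.11	1.15	C	autosomal
rs1800469	TGFB1/B9D2/TMEM91	19q13.2	1.09	G	autosomal
rs2241714	TGFB1/TMEM91/B9D2	19q13.2	1.09	C	autosomal
rs961253	BMP2/HAO1/FERMT1	20p12.3	1.12	A	autosomal
rs4813802	BMP2/HAO1/FERMT1	20p12.3	1.10	C	autosomal
rs2423279	HAO1/PLCB1	20p12.3	1.10	C	autosomal
rs5934683	SHROOM/GPR143	Xp22.2	1.04	C	x_linked
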