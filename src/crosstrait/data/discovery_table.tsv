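snp_id	a1	a2	eaf_ukb	chrom	pos	gene	analysis	n_broad	n_analysis	n_rep	p_broad	p_analysis	p_biv	p_rep_1sided	p_comb	ed	prior_reported	novel_for
rs2422320	T	C	0.43	1	73293332	NEGR1	sMDD	70017	307354	322580	4.32e-4	2.76e-6	5.25e-9	3.66e-5	1.52e-11	---	1
rs7714851	T	C	0.52	5	164475774	MAT2B	sMDD	70017	307354	322580	4.24e-6	1.09e-6	1.60e-11	5.35e-7	8.03e-16	---	1
rs9368649	A	G	0.14	6	30938883	MUC21	sMDD	70017	307354	322580	3.18e-5	1.14e-5	1.36e-8	4.75e-3	9.97e-9	---	0	Depression
rs9323497	T	C	0.05	14	67873128	PLEK2	rMDD	70017	10640	322580	3.27e-8	2.21e-4	3.05e-10	4.12e-1	4.48e-9	+++	0
rs16836940	A	G	0.22	1	150416913	RPRD2	BPD	70017	16731	322580	4.63e-6	5.32e-4	1.28e-8	2.96e-1	6.42e-8	+++	0	BPD
rs2535629	A	G	0.33	3	52833219	ITIH3	BPD	70017	16731	322580	1.89e-4	8.20e-7	4.94e-9	6.60e-3	1.10e-9	---	1
rs4765914	T	C	0.79	12	2420377	CACNA1C	BPD	70017	16731	322580	1.25e-4	6.78e-6	3.77e-9	4.24e-2	5.25e-9	+++	1
rs12407717	T	C	0.13	1	30426014	MATN1	SCZ	70017	150064	322580	7.49e-6	1.45e-4	4.91e-9	1.82e-1	1.89e-8	++-	0	SCZ
rs12128108	T	C	0.23	1	50293421	AGBL4	SCZ	70017	150064	322580	3.35e-5	9.18e-6	1.32e-9	6.65e-2	2.62e-9	+++	0	SCZ
rs2318763	A	G	0.17	1	150115974	VPS45	SCZ	70017	150064	322580	1.91e-4	5.84e-9	1.48e-11	1.69e-1	4.84e-11	+++	0
rs7597593	T	C	0.62	2	185533580	ZNF804A	SCZ	70017	150064	322580	1.89e-4	1.47e-9	4.80e-12	2.14e-2	2.53e-12	+++	0	Depression
rs2535629	A	G	0.33	3	52833219	ITIH3	SCZ	70017	150064	322580	1.89e-4	1.33e-8	8.95e-11	6.60e-3	2.04e-11	---	1
rs1966136	A	C	0.41	3	61153578	FHIT	SCZ	70017	150064	322580	1.03e-7	8.00e-4	2.52e-9	6.45e-4	6.13e-11	---	1	SCZ
rs911186	A	G	0.23	6	27150599	MIR3143	SCZ	70017	150064	322580	4.21e-4	1.93e-14	3.90e-16	2.00e-3	3.50e-18	+++	0	Depression
rs1265099	A	G	0.41	6	31105413	PSORS1C2	SCZ	70017	150064	322580	1.25e-4	1.62e-6	1.06e-9	6.90e-3	2.39e-10	+++	0	Depression, SCZ
rs389883	T	G	0.68	6	31947460	STK19	SCZ	70017	150064	322580	9.65e-4	1.35e-7	1.38e-9	2.37e-5	1.33e-12	+++	0	Depression, SCZ
rs4976976	A	G	0.40	8	143311653	TSNARE1	SCZ	70017	150064	322580	5.14e-4	1.19e-10	2.28e-12	9.25e-2	4.36e-12	---	0
rs2026194	T	C	0.24	9	85082899	SPATA31D1	SCZ	70017	150064	322580	4.00e-4	5.40e-6	1.09e-8	3.62e-3	1.74e-9	+++	0	Depression, SCZ
rs10774037	A	G	0.79	12	2420526	CACNA1C	SCZ	70017	150064	322580	6.62e-5	2.47e-9	6.40e-12	4.48e-2	7.94e-12	---	1
rs2182139	T	C	0.75	14	60149233	RTN1	SCZ	70017	150064	322580	2.38e-4	9.19e-6	9.97e-9	1.86e-3	8.31e-10	+++	0	Depression, SCZ
rs4906335	A	C	0.28	14	104021141	BAG5	SCZ	70017	150064	322580	5.78e-4	1.82e-12	4.52e-14	7.25e-4	9.42e-16	+++	1
rs4843613	T	C	0.83	16	87489698	ZCCHC14	SCZ	70017	150064	322580	4.13e-5	2.00e-5	3.40e-9	4.48e-2	4.70e-9	+++	0	SCZ
rs9951150	A	G	0.46	18	52821124	TCF4	SCZ	70017	150064	322580	5.73e-4	2.31e-6	3.70e-8	4.64e-3	7.08e-9	---	0	Depression, SCZ
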