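sample_id	sex	band	chrom	start	end	cnv_type	printed_size_mb	inheritance	n_refseq_genes	first_marker_id	last_marker_id	flank_before_id	flank_after_id
fetus_14	FEMALE	Xp22.2-Xp22.32	X	4642016	11935042	DEL	7.2	Yes	23	rs5915786	rs5978478	rs6530416	rs1526798
fetus_14	FEMALE	Xp22.32-Xp22.33	X	2700157	4628697	DUP	1.93	Yes	10	rs5916528	rs7881910	Telomer	rs7391672
fetus_1	MALE	6q27	6	170140184	170919470	DEL	0.78	Yes	13	rs9383520	rs12530134	rs9478086	Telomer
fetus_2	FEMALE	2q32.1-2q32.2	2	189363100	189750863	DUP	0.39	n.t.	2	rs7424417	rs997277	rs7574262	rs1516445
fetus_2	FEMALE	16q12.11	16	47074235	47174275	DEL	0.10	n.t.	1	rs4967746	rs16952589	rs12930613	rs11863453
fetus_3	MALE	3q26.1	3	165553646	166065099	DUP	0.51	n.t.	1	rs4680608	rs2863381	rs1355538	rs10936492
fetus_4	MALE	3p26.3	3	1436664	1511108	DEL	0.07	n.t.	1	rs9840732	rs9856251	rs3843386	rs172171
fetus_5	MALE	4q31.23	4	148727355	148903388	DEL	0.18	n.t.	1	rs17023845	rs13129809	rs6845560	rs10025443
fetus_6	FEMALE	4q13.3	4	73812806	74058406	DUP	0.25	n.t.	2	rs1381015	rs10028486	rs11941162	rs714825
fetus_6	FEMALE	8q24.3	8	142295965	142382757	DUP	0.09	n.t.	2	rs7819263	rs10112201	rs3824233	rs6578185
fetus_7	FEMALE	9p23	9	10144584	11398305	DUP	1.25	n.t.	2	rs12552479	rs1335475	rs1441400	rs7038987
fetus_8	MALE	18p11.21	18	12456559	12643193	DEL	0.19	n.t.	1	rs522631	rs1592643	rs496485	rs9960249
fetus_9	MALE	2q37.3	2	241623894	241722445	DUP	0.10	n.t.	2	rs4676385	rs2288750	rs2975778	rs4234121
fetus_9	MALE	3q13.32	3	118730933	118812027	DUP	0.08	n.t.	1	rs4687836	rs2917080	rs9878706	rs2903301
fetus_10	FEMALE	17p11.2-17p12	17	15063832	17493810	DUP	2.43	n.t.	42	rs4792576	rs4646341	rs9907064	rs12449964
fetus_11	FEMALE	16p12.2	16	21839340	22409463	DEL	0.57	No paternal inheritance	7	rs670841	rs8062140	rs8054407	rs9928431
fetus_12	MALE	6p25.1-6p25.3	6	212548	4864581	DEL	4.65	Yes	35	rs6930285	rs808601	Telomer	rs3804547
fetus_13	MALE	Xp22.11	X	23799472	24012381	DUP	0.21	Maternal	4	rs5925934	rs10521917	rs7879340	rs6526366
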