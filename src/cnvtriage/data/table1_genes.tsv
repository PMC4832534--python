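symbol	chrom	start	end	cns_flag
ERMARD	6	170572365	170630068	1
GULP1	2	189159761	189463482	1
NETO2	16	47103786	47148638	1
BCHE	3	165490692	165555260	1
CNTN6	3	1134260	1445420	1
ARHGAP10	4	148559646	148888949	1
COX18	4	73896017	73929141	1
GPR20	8	142367103	142373322	1
PTPRD	9	8314246	10612723	1
SPIRE1	18	12456855	12617174	1
KIF1A	2	241653061	241759770	1
IGSF11	3	118620829	118869543	1
RASD1	17	17490000	17496395	1
CDR2	16	22251835	22304695	1
FOXC1	6	1610681	1614129	1
KLHL15	X	23900276	23957599	1
MID1	X	10413350	10851809	1
PRKX	X	3522383	3631649	1
AQP12A	2	241708151	241710612	0
SAT1	X	23801918	23804958	0
DIRC1	2	189405398	189463000	0
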