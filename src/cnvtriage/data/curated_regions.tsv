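label	chrom	start	end	required_type	tier	citation
6q27_terminal_deletion	6	168500000	171115067	DEL	ESTABLISHED	6q27 terminal deletions recurrently observed with brain anomalies (ACC, hydrocephalus, cerebellar malformations)
FOXC1_6p25_deletion	6	1610681	1614129	DEL	ESTABLISHED	FOXC1 deletions and point mutations are a major contributor to Dandy-Walker malformation
PTLS_17p11.2_duplication	17	16100000	20300000	DUP	ESTABLISHED	17p11.2 duplications associated with Potocki-Lupski syndrome neurobehavioral phenotype
MID1_Xp22.2_deletion	X	10413350	10851809	DEL	ESTABLISHED	MID1 loss associated with X-linked Opitz syndrome including ACC
Xp22.32_Xp22.33_duplication	X	2700000	4700000	DUP	ESTABLISHED	Xp22.32-p22.33 duplications with intellectual disability and corpus-callosum anomalies
CNTN6_3p26.3	3	1134260	1445420	ANY	CANDIDATE	CNTN6 dosage changes associated with neurodevelopmental disorders and brain anomalies
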