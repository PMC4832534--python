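sample_id	chrom	start	end	cnv_type	copy_state	log_bayes_factor	n_markers
control_0412	2	241623894	241722445	DUP	3	44.10	12
control_0877	3	118730933	118812027	DUP	3	38.70	9
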