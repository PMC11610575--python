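#chrom	start	end	locus_id	motif	pathogenic_min	cutoff_unit
chr4	3074876	3074933	HTT	CAG	40	units
chr19	45770204	45770266	DMPK	CTG	50	units
chrX	147912050	147912110	FMR1	CGG	200	units
chr4	39348424	39348479	RFC1	AAAAG	400	units
chr19	13207858	13207897	CACNA1A	CAG	20	units
chrX	31284556	31284666	DMD	TTC	59	units
chrX	67545316	67545419	AR	CAG	38	units
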