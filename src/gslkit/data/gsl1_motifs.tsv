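motif_id	pattern	function_note
BIHD1OS	TGTCA	Disease responsive
GT1GMSCAM4	GAAAAA	Pathogen- and salt-induced expression (GT-1 motif)
IBOXCORE	GATAA	Light regulated (I box)
MYB1AT	WAACCA	Dehydration response (MYB recognition site)
MYBST1	GGATA	Transcriptional activator (MybSt1 core motif)
RAV1AAT	CAACA	Rosette leaf- and root-specific
SREATMSD	TTATCC	Axillary bud-specific (sugar-repressive element)
WUSATAg	TTAATGG	Root apical meristem-specific
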