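motif_id	pattern	function_note
MYBPLANT	MACCWAMC	Transcriptional activator (MYB binding site)
RYREPEATVFLEB4	CATGCATG	Tissue-specific expression (RY repeat motif)
SURE1STPAT21	AATAGAAAA	Sucrose responsive element (tuber storage protein regulation)
CPBCSPOR	TATTAG	Cytokinin responsive
GT1GMSCAM4	GAAAAA	Pathogen- and salt-responsive (GT-1 motif)
MYBGAHV	TAACAAA	Gibberellin responsive
MYBST1	GGATA	Transcriptional activator (MybSt1 core motif)
NTBBF1ARROLB	ACTTTA	Auxin induction and tissue-specific expression
SREATMSD	TTATCC	Axillary bud-specific (sugar-repressive element)
WBOXHVISO1	TGACT	Sugar responsive
WUSATAg	TTAATGG	Root apical meristem-specific
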