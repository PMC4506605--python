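gene_symbol	drug
FN1	Ocriplasmin
EGFR	Cetuximab
EGFR	AEE 788
EGFR	panitumumab
EGFR	BMS-599626
EGFR	varlitinib
EGFR	XL647
EGFR	afatinib
EGFR	sapitinib
EGFR	cetuximab/irinotecan
EGFR	erlotinib/gemcitabine
EGFR	lapatinib/letrozole
EGFR	canertinib
EGFR	gefitinib
EGFR	neratinib
EGFR	PD 153035
EGFR	lapatinib
EGFR	vandetanib
EGFR	erlotinib
ITGAV	Abciximab
ITGAV	CNTO 95
ITGAV	cilengitide
ITGB3	Abciximab
ITGB3	TP 9201
ITGB3	cilengitide
ITGB3	tirofiban
COL1A1	Collagenase clostridium histolyticum
ITGB5	Cilengitide
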