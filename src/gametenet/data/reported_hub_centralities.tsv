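gene_symbol	protein_family	degree	betweenness	closeness
ITGB1	Integrins	33	0.2	0.5
FN1	Fibronectin	30	0.1	0.5
EGFR	Epidermal growth factor receptors	26	0.2	0.5
ITGA3	Integrins	25	0.03	0.5
ITGAV	Integrins	24	0.03	0.5
ITGB3	Integrins	23	0.02	0.5
COL1A1	Collagens	22	0.02	0.5
CD9	Tetraspanins	21	0.1	0.5
ITGB4	Integrins	20	0.04	0.5
ITGA5	Integrins	19	0.04	0.5
ITGB8	Integrins	18	0.01	0.4
ITGB5	Integrins	17	0.01	0.4
ITGA2	Integrins	17	0.01	0.4
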