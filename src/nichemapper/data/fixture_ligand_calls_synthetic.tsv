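ligand	population	log2fc	p	pct_in	pct_out
CDO1	osteo	7.2	1e-09	0.85	0.02
APOE	MSC	6.1	1e-08	0.90	0.05
KITLG	MSC	3.4	1e-07	0.75	0.04
THBS1	arteriolar	2.8	1e-06	0.70	0.06
SEMA3A	chondrocyte	2.2	1e-06	0.65	0.05
SYNL_ADSL	MSC	2.0	1e-05	0.60	0.05
SYNL_CD33	sinusoidal	1.8	1e-05	0.55	0.04
SYNL_PRKD2	osteo	2.5	1e-06	0.60	0.03
SYNL1	MSC	1.6	1e-04	0.50	0.05
SYNL2	osteo	1.7	1e-04	0.55	0.05
SYNL3	arteriolar	1.5	2e-04	0.45	0.04
SYNL4	sinusoidal	1.9	1e-05	0.50	0.03
SYNL5	MSC	2.1	1e-05	0.60	0.05
SYNL6	fibroblast	1.4	5e-04	0.40	0.04
SYNL7	pericyte	1.6	2e-04	0.45	0.04
PVR	MSC	0.3	0.62	0.20	0.18
SYNL_NE1	osteo	0.1	0.81	0.15	0.14
SYNL_NE2	arteriolar	-0.2	0.90	0.10	0.12
SYNL_NE3	sinusoidal	0.0	0.95	0.08	0.08
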