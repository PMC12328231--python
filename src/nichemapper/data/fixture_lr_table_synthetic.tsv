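ligand	receptor	source
CDO1	SLC6A6	curated
APOE	LDLR	curated
KITLG	KIT	curated
THBS1	CD47	curated
SEMA3A	NRP1	curated
SYNL_ADSL	ADSL	curated
SYNL_CD33	CD33	curated
SYNL_PRKD2	PRKD2	curated
SYNL1	SYNR1	curated
SYNL2	SYNR2	curated
SYNL3	SYNR3	curated
SYNL4	SYNR4	curated
SYNL5	SYNR5	curated
SYNL6	SYNR6	curated
SYNL7	SYNR7	curated
PVR	CD96	curated
SYNL_NE1	LGALS3BP	curated
SYNL_NE2	CD274	curated
SYNL_NE3	CD3D	curated
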