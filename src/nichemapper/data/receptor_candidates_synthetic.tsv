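gene	category
SLC6A6	both
LDLR	both
KIT	both
CD47	both
NRP1	both
ADSL	both
CD33	both
PRKD2	both
CHST11	both
ST3GAL4	both
MR1	both
LGALS3BP	both
SYNR1	both
ACAA1	AML_only
CLCN6	AML_only
CHPF2	AML_only
CTSK	AML_only
ATP6AP1	AML_only
CTSD	AML_only
PNPLA6	AML_only
DMXL2	AML_only
TUBB6	AML_only
MAN2B2	AML_only
TMCO3	AML_only
CD96	AML_only
CD274	AML_only
SYNR2	AML_only
SYNR3	AML_only
SYNR4	AML_only
SYNR5	AML_only
SYNR6	AML_only
CLN3	bcCML_only
MGAT4B	bcCML_only
MYH9	bcCML_only
PIGG	bcCML_only
TSPAN15	bcCML_only
CD3D	bcCML_only
SYNR7	bcCML_only
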