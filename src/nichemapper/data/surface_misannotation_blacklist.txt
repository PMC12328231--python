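# Genes misannotated as cell-surface in the Cell Surface Protein Atlas,
# removed from the receptor candidate pool during curation.
CHST11
ST3GAL4
ACAA1
CLCN6
CHPF2
CTSK
ATP6AP1
CTSD
PNPLA6
DMXL2
TUBB6
MAN2B2
CLN3
MGAT4B
MYH9
PIGG
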