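# Default antigen-presentation pathway gene list (22 genes, literature-based).
# One gene symbol per line; override with --apg-list / EscapeConfig.apg_genes.
B2M
CALR
CANX
PDIA3
TAP1
TAP2
TAPBP
TAPBPL
ERAP1
ERAP2
NLRC5
RFX5
RFXAP
RFXANK
CIITA
PSMB8
PSMB9
PSME1
PSME2
PSME3
IRF1
HSPA5
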