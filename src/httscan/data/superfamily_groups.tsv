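superfamily	group
BEL	LTR retrotransposon
Copia	LTR retrotransposon
DIRS	LTR retrotransposon
Gypsy	LTR retrotransposon
CR1	Non-LTR retrotransposon
Crack	Non-LTR retrotransposon
Daphne	Non-LTR retrotransposon
I	Non-LTR retrotransposon
Ingi	Non-LTR retrotransposon
Jockey	Non-LTR retrotransposon
Kiri	Non-LTR retrotransposon
L2B	Non-LTR retrotransposon
Nimb	Non-LTR retrotransposon
Penelope	Non-LTR retrotransposon
RTE	Non-LTR retrotransposon
RTEX	Non-LTR retrotransposon
EnSpm/CACTA	DNA transposon
Harbinger	DNA transposon
Mariner/Tc1	DNA transposon
hAT	DNA transposon
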