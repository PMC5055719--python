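family	source_species	canonical_superfamily	canonical_group
Harbinger-N1_LVa	Litopenaeus vannamei	Harbinger	DNA transposon
DNA8-1_LVa	Litopenaeus vannamei	Unknown	DNA transposon
BEL-1_LVa-I	Litopenaeus vannamei	BEL	LTR retrotransposon
BEL-2_LVa	Litopenaeus vannamei	BEL	LTR retrotransposon
Gypsy-12_LVa-I	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-14_LVa-I	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-16_LVa	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-17_LVa	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-18_LVa	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-1_LVa-I	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-3_LVa-I	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-3_LVa-LTR	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-4_LVa-I	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Gypsy-5_LVa-I	Litopenaeus vannamei	Gypsy	LTR retrotransposon
Penelope-6_LVa	Litopenaeus vannamei	Penelope	Non-LTR retrotransposon
Ingi-1_LVa	Litopenaeus vannamei	Ingi	Non-LTR retrotransposon
Jockey-1_LVa	Litopenaeus vannamei	Jockey	Non-LTR retrotransposon
Nimb-N2_LVa	Litopenaeus vannamei	Nimb	Non-LTR retrotransposon
Nimb-2_LVa	Litopenaeus vannamei	Nimb	Non-LTR retrotransposon
Nimb-1_LVa	Litopenaeus vannamei	Nimb	Non-LTR retrotransposon
Penelope-1_LVa	Litopenaeus vannamei	Penelope	Non-LTR retrotransposon
Penelope-2_LVa	Litopenaeus vannamei	Penelope	Non-LTR retrotransposon
Penelope-3_LVa	Litopenaeus vannamei	Penelope	Non-LTR retrotransposon
Penelope-4_LVa	Litopenaeus vannamei	Penelope	Non-LTR retrotransposon
Penelope-5_LVa	Litopenaeus vannamei	Penelope	Non-LTR retrotransposon
Penelope-8_LVa	Litopenaeus vannamei	Penelope	Non-LTR retrotransposon
RTE-1_LVa	Litopenaeus vannamei	RTE	Non-LTR retrotransposon
RTE-2_LVa	Litopenaeus vannamei	RTE	Non-LTR retrotransposon
RTE-3_LVa	Litopenaeus vannamei	RTE	Non-LTR retrotransposon
NonLTR-1_LVa	Litopenaeus vannamei	Unknown	Non-LTR retrotransposon
TE-1_LVa	Litopenaeus vannamei	Unknown	Unknown
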