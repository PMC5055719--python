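priority	label	include_terms	exclude_terms	excluded
0	Penaeidae	Penaeidae		1
1	Arthropoda	Arthropoda	Penaeidae	0
2	Actinopterygii	Actinopterygii		0
3	Mollusca	Mollusca		0
4	Echinodermata	Echinodermata		0
5	Brachiopoda	Brachiopoda		0
6	Enteropneusta	Enteropneusta		0
7	Annelida	Annelida		0
8	Alveolata	Alveolata		0
9	Cyclostomata	Cyclostomata		0
10	Cnidaria	Cnidaria		0
11	Nematoda	Nematoda		0
12	Platyhelminthes	Platyhelminthes		0
13	Bacteria	Bacteria		0
14	Viruses	Viruses		0
15	Embryophyta	Embryophyta		0
16	Mammalia	Mammalia		0
17	Aves	Aves		0
18	Other	*		0
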