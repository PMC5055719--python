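family	has_hit	taxon	organism	e_value	identity_pct	query_coverage_pct
BEL-1_LVa-I	1	Brachiopoda	Lingula anatina	8.63e-30	70	6
Gypsy-14_LVa-I	1	Mollusca	Lottia gigantea	9.36e-29	70	6
Gypsy-17_LVa	1	Actinopterygii	Danio rerio	3.21e-11	84	3
Gypsy-3_LVa-LTR	1	Actinopterygii	Salmo salar	1.00e-43	70	30
Gypsy-4_LVa-I	1	Nematoda	Trichinella spiralis	1.90e-23	72	7
Penelope-6_LVa	1	Arthropoda	Limulus polyphemus	7.99e-14	73	6
RTE-1_LVa	1	Actinopterygii	Oryzias latipes	1.86e-28	66	22
RTE-2_LVa	1	Echinodermata	Strongylocentrotus purpuratus	1.31e-45	65	21
RTE-3_LVa	1	Echinodermata	Strongylocentrotus purpuratus	6.34e-48	80	7
Gypsy-18_LVa	0
Gypsy-5_LVa-I	0
Nimb-1_LVa	0
Nimb-2_LVa	0
Penelope-1_LVa	0
Penelope-3_LVa	0
Penelope-8_LVa	0
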