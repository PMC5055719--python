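priority	label	include_terms	exclude_terms	excluded
0	shrimp	Penaeidae		0
1	amphibians	Amphibia,Testudines,Annelida,Crocodylia		0
2	aquatic animals	Mollusca,Actinopterygii,Echinodermata,Brachiopoda,Enteropneusta,Tunicata,Porifera,Rotifera,Choanoflagellida,Placozoa,Rhizaria,Cyclostomata,Coelacanthiformes,Cnidaria,Euglenozoa,Priapulida,Apusozoa,Heterolobosea,Dipnoi,Chondrichthyes,Cephalochordata		0
3	aquatic plants	Viridiplantae,Haptophyceae,Stramenopiles	Embryophyta	0
4	arthropods	Arthropoda	Penaeidae	0
5	land animals	Squamata,Mammalia,Aves		0
6	land plants	Embryophyta		0
7	microorganisms	Bacteria,Fungi,Viruses		0
8	parasites	Nematoda,Platyhelminthes,Amoebozoa,Jakobida,Alveolata		0
9	other	*		0
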