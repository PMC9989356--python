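species	lineage	class	Shaker	Shab	Shaw	Shal	Eag	Erg	Elk	KCNQ
Acropora_digitifera	Anthozoa	Hexacorallia	16	0	10	6	1	1	1	1
Stylophora_pistillata	Anthozoa	Hexacorallia	20	0	11	10	1	4	1	1
Exaiptasia_pallida	Anthozoa	Hexacorallia	19	1	12	13	1	2	1	0
Nematostella_vectensis	Anthozoa	Hexacorallia	20	1	12	12	1	5	1	1
Renilla_muelleri	Anthozoa	Octocorallia	17	0	10	5	2	2	0	1
Rhopilema_esculentum	Medusozoa	Scyphozoa	21	1	7	3	1	2	1	4
Sanderia_malayensis	Medusozoa	Scyphozoa	22	1	6	3	1	2	1	4
Hydra_vulgaris	Medusozoa	Hydrozoa	16	1	15	2	4	4	0	7
Homo_sapiens	Bilateria	Mammalia	8	2	4	3	2	3	3	5
Drosophila_melanogaster	Bilateria	Insecta	1	1	2	1	1	1	1	1
Caenorhabditis_elegans	Bilateria	Nematoda	1	6	3	1	1	1	0	3
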