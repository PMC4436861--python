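order	family	family_size	known_halophytes	pct_halophytes_in_family	taxonomic_pattern	subtree_size	pct_species_in_subtree	halophytes_in_subtree	pct_halophytes_in_subtree	pct_halophytes_sampled	inferred_origins	noto	p_noto	p_sscd
Apiales	Apiaceae	3780	33	0.9	expected	1082	28.6	26	2.4	78.8	22	1.2	0.00	0.00
Arecales	Arecaceae	2361	35	1.5	more	415	17.6	19	4.6	54.3	15	1.3	0.06	0.00
Asterales	Asteraceae	23600	267	1.1	expected	4618	19.6	97	2.1	36.3	87	1.1	0.00	0.00
Asterales	Goodeniaceae	430	6	1.4	expected	69	16.0	6	8.7	100.0	6	1.0	0.09	0.01
Brassicales	Brassicaceae	3710	38	1.0	expected	1355	36.5	21	1.5	55.3	19	1.1	0.00	0.00
Caryophyllales	Amaranthaceae	2275	507	22.3	more	613	26.9	262	42.7	51.7	54	4.9	0.16	0.00
Caryophyllales	Tamaricaceae	90	55	61.1	more	42	46.7	29	69.0	52.7	1	29.0	1.00	1.00
Cucurbitales	Cucurbitaceae	960	14	1.5	expected	247	25.7	9	3.6	64.3	8	1.1	0.14	0.02
Ericales	Primulaceae	2590	14	0.5	fewer	546	21.1	8	1.5	57.1	5	1.6	0.65	0.55
Fagales	Casuarinaceae	95	12	12.6	more	88	92.6	12	13.6	100.0	7	1.7	0.46	0.08
Gentianales	Rubiaceae	13150	13	0.1	fewer	1393	10.6	7	0.5	53.8	7	1.0	0.09	0.01
Lamiales	Acanthaceae	4000	18	0.5	fewer	498	12.5	9	1.8	50.0	5	1.8	0.75	0.54
Lamiales	Lamiaceae	7173	27	0.4	fewer	941	13.1	14	1.5	51.9	11	1.3	0.14	0.05
Malpighiales	Euphorbiaceae	5735	42	0.7	fewer	1047	18.3	16	1.5	38.1	14	1.1	0.03	0.00
Malpighiales	Rhizophoraceae	149	19	12.8	more	40	26.8	18	45.0	94.7	6	3.0	0.52	0.71
Myrtales	Combretaceae	500	12	2.4	more	25	5.0	8	32.0	66.7	6	1.3	0.23	0.25
Myrtales	Lythraceae	620	21	3.4	more	119	19.2	14	11.8	66.7	8	1.8	0.53	0.46
Myrtales	Myrtaceae	4620	47	1.0	expected	612	13.2	20	3.3	42.6	19	1.1	0.00	0.00
Poales	Cyperaceae	5430	121	2.2	more	1087	20.0	57	5.2	47.1	52	1.1	0.00	0.00
Poales	Juncaceae	430	22	5.1	more	124	28.8	12	9.7	54.5	8	1.5	0.31	0.45
Poales	Poaceae	11160	335	3.0	more	2291	20.5	173	7.6	51.6	127	1.4	0.00	0.00
Rosales	Rosaceae	2520	9	0.4	fewer	1010	40.1	8	0.8	88.9	8	1.0	0.05	0.05
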