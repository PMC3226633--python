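species	Bumpkin	Calf	Grape	Great Brewster	Langlee	Ragged	Snake	Spectacle	Thompson	Worlds End
Amblyopone pallipes	1	2	2	2	5	1	0	0	12	2
Anergates atratulus	0	0	0	0	0	0	0	0	1	0
Aphaenogaster fulva	0	1	0	0	0	0	0	0	0	0
Aphaenogaster rudis Complex	24	27	20	11	51	24	0	0	84	90
Brachymyrmex depilis	3	0	5	6	13	1	0	1	0	2
Camponotus americanus	0	0	0	0	0	0	0	0	0	1
Camponotus caryae	0	0	0	0	1	0	0	0	1	2
Camponotus nearcticus	1	2	1	0	2	12	0	0	3	3
Camponotus novaeboracensis	0	1	0	0	0	1	0	0	0	0
Camponotus pennsylvanicus	6	0	23	0	19	45	0	3	20	45
Crematogaster cerasi	0	1	13	16	8	22	4	4	11	17
Crematogaster lineolata	13	1	1	12	11	24	7	11	27	4
Formica dolosa	0	0	0	0	0	0	0	0	0	4
Formica incerta	0	1	14	0	5	2	10	8	20	10
Formica lasioides	0	0	1	0	0	0	0	0	0	0
Formica neogagates	1	0	0	0	3	0	0	0	0	6
Formica subsericea	25	0	12	0	9	32	0	0	19	27
Lasius alienus	9	1	34	5	4	1	2	27	18	7
Lasius claviger	0	0	1	0	0	0	0	0	1	1
Lasius interjectus	2	0	3	1	0	0	0	0	2	0
Lasius latipes	0	0	4	0	0	0	0	0	1	0
Lasius nearcticus	0	0	0	4	4	1	0	0	0	7
Lasius neoniger	8	1	13	20	3	0	9	12	61	6
Lasius pallitarsis	0	11	5	8	0	0	1	2	6	3
Lasius subglaber	0	0	0	0	1	0	0	0	0	0
Lasius umbratus	1	0	3	0	2	0	0	0	5	5
Monomorium emarginatum	0	0	0	0	0	0	6	2	2	0
Myrmecina americana	0	0	0	0	0	0	6	0	2	0
Myrmica "sculptilis"	3	1	14	0	2	0	0	0	0	25
Myrmica "smithana"	9	0	5	1	0	0	0	0	0	14
Myrmica americana	0	0	0	0	0	0	0	2	1	2
Myrmica fracticornis	1	0	16	0	0	0	1	6	2	1
Myrmica pinetorum	0	0	2	0	1	0	0	0	1	1
Myrmica punctiventris	9	0	30	8	6	34	0	0	20	30
Myrmica rubra	19	54	15	72	4	3	26	6	57	15
Myrmica scabrinodis	0	0	5	0	0	0	1	9	6	1
Nylanderia flavipes	0	0	0	0	0	0	0	0	59	0
Ponera pennsylvanica	6	12	17	10	9	23	13	2	49	6
Prenolepis imparis	4	2	29	3	22	5	15	1	64	18
Protomagnathus americanus	0	0	1	0	0	0	0	0	0	0
Pyramica metazytes	0	0	0	0	0	0	0	0	1	0
Solenopsis molesta	11	0	18	11	2	5	3	0	36	1
Stenamma brevicorne	1	14	17	28	2	3	13	2	26	12
Stenamma impar	2	6	20	0	6	9	3	0	12	5
Stenamma schmitti	1	1	12	0	2	4	0	0	1	2
Tapinoma sessile	14	6	32	30	6	9	12	16	12	17
Temnothorax ambiguus	1	13	18	19	0	3	11	14	8	5
Temnothorax curvispinosus	6	2	51	1	11	9	15	4	14	9
Temnothorax longispinosus	0	0	4	2	13	21	1	2	12	8
Temnothorax schaumii	0	0	0	0	0	0	0	0	0	2
Tetramorium caespitum	9	32	48	59	9	25	17	68	56	9
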