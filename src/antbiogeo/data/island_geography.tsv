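island	area_km2	isolation_km	samples	s_obs	abundance
Bumpkin	0.12	0.64	53	27	885
Calf	0.07	3.29	117	22	972
Grape	0.22	0.47	179	37	4506
Great Brewster	0.08	2.36	130	22	1481
Langlee	0.02	0.52	80	32	977
Ragged	0.01	0.32	97	27	1378
Snake	0.03	0.35	50	22	752
Spectacle	0.35	1.92	138	22	1251
Thompson	0.54	0.51	383	40	3993
Worlds End	1.08	0.00	193	40	1366
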