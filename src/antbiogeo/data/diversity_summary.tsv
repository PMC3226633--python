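island	s_obs_year	s_obs_week_mean	s_obs_week_sd	s_year_mean	s_year_sd	s_week_mean	s_week_sd	alpha_year_mean	alpha_year_sd	alpha_week_mean	alpha_week_sd	turnover_space_mean	turnover_space_sd	turnover_time_mean	turnover_time_sd
Bumpkin	27	10.38	8.11	30.33	2.08	29.32	8.08	2.53	3.34	3.60	2.11	7.54	2.92	0.73	0.10
Calf	22	6.07	3.12	27.38	3.82	12.64	2.96	1.24	1.41	1.45	0.54	9.85	3.20	0.61	0.11
Grape	36	10.76	7.35	37.70	1.33	23.87	5.98	1.89	2.37	2.18	0.83	9.58	2.79	0.49	0.17
Great Brewster	22	9.73	4.41	23.22	1.17	23.32	9.38	1.70	1.94	2.02	0.64	9.03	3.07	0.66	0.12
Langlee	30	11.62	6.12	32.98	1.32	18.75	5.92	2.06	2.72	2.41	1.27	9.84	8.79	0.53	0.13
Ragged	25	9.33	6.56	26.13	1.22	19.31	3.44	2.31	2.04	2.61	0.71	6.72	1.69	0.66	0.18
Snake	21	9.00	4.82	21.30	0.69	19.06	3.48	3.00	2.78	3.38	1.35	5.24	1.70	0.54	0.20
Spectacle	21	6.57	3.03	23.03	1.22	14.30	2.25	1.20	1.60	1.60	0.41	9.60	1.86	0.61	0.16
Thompson	38	12.14	6.93	39.36	1.54	21.62	4.45	1.38	2.04	1.84	0.82	13.80	10.56	0.58	0.10
Worlds End	39	10.33	7.49	42.49	2.03	25.51	4.73	1.66	2.00	1.96	1.00	10.73	4.12	0.40	0.17
total BHI	51	25.09	7.00	51.08	1.00	30.72	4.36	1.69	2.16	2.14	1.07	9.76	5.74	0.56	0.17
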