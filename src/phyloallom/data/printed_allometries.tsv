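group	trait	n	slope	ci_s_low	ci_s_high	p	intercept	ci_i_low	ci_i_high	lambda
all	egg_volume	1362	0.18	0.13	0.23	<0.01	-1.99	-2.78	-1.19	0.92
all	egg_diameter	1362	0.06	0.04	0.08	<0.01	0.43	0.17	0.70	0.92
all	clutch_size	1860	0.45	0.41	0.50	<0.01	1.22	0.46	1.98	0.90
all	clutch_volume	1240	0.71	0.66	0.77	<0.01	-0.78	-1.20	-0.37	0.49
all	annual_clutch_number	35	0.01	-0.07	0.08	0.86	0.05	-0.27	0.38	0.94
all	annual_clutch_volume	33	0.12	-0.07	0.32	0.20	0.63	-0.75	2.01	1.02
all	incubation_time	191	-0.03	-0.14	0.07	0.53	1.56	0.92	2.19	0.91
all	hatchling_total_length	105	0.10	0.04	0.16	<0.01	1.19	0.85	1.52	0.99
all	hatchling_svl	42	0.02	-0.05	0.10	0.50	0.73	0.36	1.10	1.04
all	larval_period	167	0.07	-0.01	0.16	0.10	1.99	1.46	2.51	0.93
all	metamorphosis_total_length	204	0.14	0.09	0.19	<0.01	1.43	1.17	1.69	0.82
all	metamorphosis_svl	65	0.17	0.11	0.24	<0.01	1.11	0.84	1.38	0.84
all	juvenile_mass	22	0.55	0.28	0.81	<0.01	-0.70	-1.21	-0.19	0.62
all	size_at_maturity	237	0.21	0.18	0.24	<0.01	1.68	1.51	1.85	0.74
all	age_at_maturity	418	0.11	0.07	0.15	<0.01	0.26	-0.01	0.53	0.84
all	max_longevity	524	0.14	0.10	0.18	<0.01	0.81	0.59	1.04	0.55
frogs	egg_volume	1174	0.16	0.10	0.22	<0.01	-2.17	-2.74	-1.61	0.89
frogs	egg_diameter	1174	0.05	0.03	0.07	<0.01	0.37	0.18	0.56	0.89
frogs	clutch_size	1625	0.49	0.44	0.54	<0.01	1.76	1.21	2.31	0.87
frogs	clutch_volume	1076	0.74	0.68	0.80	<0.01	-0.54	-0.84	-0.25	0.38
frogs	annual_clutch_number	14	0.15	0.02	0.29	0.03	0.15	-0.16	0.47	0.93
frogs	annual_clutch_volume	14	1.26	0.87	1.64	<0.01	-0.62	-1.54	0.29	0.95
frogs	incubation_time	126	-0.11	-0.24	0.02	0.09	1.11	0.62	1.60	0.94
frogs	hatchling_total_length	55	0.02	-0.09	0.13	0.72	0.85	0.55	1.15	0.97
frogs	hatchling_svl	28	0.04	-0.09	0.16	0.54	0.50	0.21	0.79	1.09
frogs	larval_period	95	0.02	-0.07	0.11	0.69	1.73	1.40	2.05	0.92
frogs	metamorphosis_total_length	115	0.14	0.07	0.20	<0.01	1.25	1.06	1.44	0.62
frogs	metamorphosis_svl	58	0.16	0.10	0.22	<0.01	0.93	0.81	1.06	0.52
frogs	juvenile_mass	15	0.51	0.18	0.84	0.01	-0.76	-1.28	-0.24	0.62
frogs	size_at_maturity	121	0.27	0.24	0.29	<0.01	1.30	1.26	1.33	-0.02
frogs	age_at_maturity	255	0.13	0.08	0.18	<0.01	0.20	-0.01	0.41	0.79
frogs	max_longevity	365	0.15	0.10	0.19	<0.01	0.78	0.59	1.00	0.57
salamanders	egg_volume	173	0.28	0.17	0.40	<0.01	-1.88	-2.38	-1.37	0.82
salamanders	egg_diameter	173	0.09	0.06	0.13	<0.01	0.47	0.30	0.64	0.82
salamanders	clutch_size	203	0.21	0.08	0.35	<0.01	1.53	0.98	2.07	0.74
salamanders	clutch_volume	152	0.50	0.34	0.66	<0.01	-0.28	-0.78	0.21	0.56
salamanders	annual_clutch_number	18	-0.04	-0.13	0.04	0.32	-0.17	-0.35	0.01	0.47
salamanders	annual_clutch_volume	18	-0.01	-0.18	0.16	0.91	-0.02	-0.91	0.87	1.03
salamanders	incubation_time	62	0.08	-0.13	0.29	0.44	1.62	1.05	2.19	0.80
salamanders	hatchling_total_length	46	0.14	0.09	0.19	<0.01	1.10	0.95	1.25	0.98
salamanders	hatchling_svl	14	0.06	-0.01	0.14	0.10	1.03	0.93	1.12	0.87
salamanders	larval_period	72	0.14	-0.02	0.30	0.08	2.27	1.63	2.92	0.96
salamanders	metamorphosis_total_length	89	0.14	0.05	0.22	<0.01	1.66	1.39	1.93	0.91
salamanders	metamorphosis_svl	7	0.49	0.01	0.97	<0.05	1.15	0.65	1.66	0.69
salamanders	juvenile_mass	6	0.66	-0.62	1.94	0.23	-0.75	-1.88	0.38	0.13
salamanders	size_at_maturity	107	0.20	0.14	0.25	<0.01	1.72	1.56	1.88	0.58
salamanders	age_at_maturity	156	0.08	0.03	0.13	<0.01	0.43	0.24	0.62	0.74
salamanders	max_longevity	153	0.16	0.09	0.23	<0.01	1.02	0.89	1.16	0.16
caecilians	egg_volume	15	0.91	<0.01	1.81	<0.05	-2.91	-4.61	-1.21	1.02
caecilians	egg_diameter	15	0.30	<0.01	0.60	<0.05	0.12	-0.44	0.69	1.02
caecilians	clutch_size	32	0.22	0.07	0.36	<0.01	0.80	0.49	1.11	0.74
caecilians	clutch_volume	12	0.84	-0.38	2.06	0.16	-1.53	-3.23	0.16	-0.30
caecilians	hatchling_total_length	4	0.31	-0.17	0.79	0.11	1.54	0.77	2.32	-1.43
caecilians	size_at_maturity	9	0.12	0.06	0.18	<0.01	2.24	2.13	2.34	1.09
caecilians	age_at_maturity	7	0.24	0.09	0.40	0.01	0.03	-0.26	0.33	1.47
caecilians	max_longevity	6	-0.24	-0.67	0.19	0.19	1.26	0.33	2.18	-5.63
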