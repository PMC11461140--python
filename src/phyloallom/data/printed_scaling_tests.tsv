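trait	group	slope	ci_s_low	ci_s_high	significant	mte_expected	mdh_expected	mte_support	mdh_support
clutch_volume	all	0.71	0.66	0.77	yes	1	1	NO	NO
clutch_volume	frogs	0.74	0.68	0.80	yes	1	1	NO	NO
clutch_volume	salamanders	0.50	0.34	0.66	yes	1	1	NO	NO
clutch_volume	caecilians	0.84	-0.38	2.06	no	1	1	NO	NO
annual_clutch_number	all	0.01	-0.07	0.08	no	-0.25	-0.12	NO	NO
annual_clutch_number	frogs	0.15	0.02	0.29	yes	-0.25	-0.12	NO	NO
annual_clutch_number	salamanders	-0.04	-0.13	0.04	no	-0.25	-0.12	NO	NO
annual_clutch_volume	all	0.12	-0.07	0.32	no	0.75	0.88	NO	NO
annual_clutch_volume	frogs	1.26	0.87	1.64	yes	0.75	0.88	NO	YES
annual_clutch_volume	salamanders	-0.01	-0.18	0.16	no	0.75	0.88	NO	NO
incubation_time	all	-0.03	-0.14	0.07	no	0.25	0.12	NO	NO
incubation_time	frogs	-0.11	-0.23	0.02	no	0.25	0.12	NO	NO
incubation_time	salamanders	0.08	-0.13	0.32	no	0.25	0.12	NO	NO
larval_period	all	0.07	-0.01	0.16	no	0.25	0.12	NO	NO
larval_period	frogs	0.02	-0.07	0.11	no	0.25	0.12	NO	NO
larval_period	salamanders	0.14	-0.02	0.30	no	0.25	0.12	NO	NO
juvenile_mass	all	0.55	0.28	0.81	yes	1	1	NO	NO
juvenile_mass	frogs	0.51	0.18	0.84	yes	1	1	NO	NO
juvenile_mass	salamanders	0.66	-0.62	1.94	no	1	1	NO	NO
age_at_maturity	all	0.11	0.07	0.15	yes	0.25	0.12	NO	YES
age_at_maturity	frogs	0.13	0.08	0.18	yes	0.25	0.12	NO	YES
age_at_maturity	salamanders	0.08	0.03	0.10	yes	0.25	0.12	NO	NO
age_at_maturity	caecilians	0.24	0.09	0.40	yes	0.25	0.12	YES	YES
max_longevity	all	0.14	0.10	0.18	yes	0.25	0.12	NO	YES
max_longevity	frogs	0.15	0.10	0.19	yes	0.25	0.12	NO	YES
max_longevity	salamanders	0.15	0.09	0.23	yes	0.25	0.12	NO	YES
max_longevity	caecilians	-0.24	-0.67	0.19	no	0.25	0.12	NO	NO
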