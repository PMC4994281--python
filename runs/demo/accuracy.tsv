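f_r	post_rules	chromosome	cohort	mean_correct	min_correct	max_correct	mean_incorrect	max_incorrect	mean_unknown	max_unknown	pct_animals_ge80_assigned
0.00	True	chr1	ABC	92.93	78.29	100.00	0.24	1.68	6.83	21.71	97.50
0.00	True	chr1	BC	99.12	91.60	100.00	0.00	0.14	0.88	8.40	100.00
0.00	True	chr2	ABC	96.43	87.65	100.00	0.42	6.47	3.15	8.82	100.00
0.00	True	chr2	BC	97.57	91.18	100.00	0.00	0.00	2.43	8.82	100.00
10.00	True	chr1	ABC	92.98	77.24	100.00	0.42	2.10	6.60	21.36	97.50
10.00	True	chr1	BC	99.19	91.60	100.00	0.02	0.49	0.79	8.40	100.00
10.00	True	chr2	ABC	96.43	87.65	100.00	0.38	6.47	3.18	8.82	100.00
10.00	True	chr2	BC	97.52	91.18	100.00	0.05	4.12	2.43	8.82	100.00
20.00	True	chr1	ABC	94.05	77.94	100.00	0.50	5.25	5.45	19.26	100.00
20.00	True	chr1	BC	99.61	97.20	100.00	0.07	1.82	0.32	2.45	100.00
20.00	True	chr2	ABC	96.43	87.65	100.00	0.38	6.47	3.18	8.82	100.00
20.00	True	chr2	BC	97.52	91.18	100.00	0.05	4.12	2.43	8.82	100.00
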