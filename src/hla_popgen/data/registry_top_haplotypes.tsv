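# Five-locus HLA haplotype frequencies (per mille) for the national pool and
# the seven geographic regions of a Chinese donor registry.  One row per
# haplotype; `rank` is the national frequency rank.  Union of the national
# top-20 and each region's top-20.
rank	A	C	B	DRB1	DQB1	China	NE	NC	NW	EC	CC	SC	SW
1	30:01	06:02	13:02	07:01	02:02	37.00	48.06	41.47	33.69	44.96	38.26	18.72	18.93
2	02:07	01:02	46:01	09:01	03:03	24.64	13.78	14.43	17.05	25.56	30.70	33.94	31.30
3	33:03	03:02	58:01	03:01	02:01	24.00	11.33	12.47	14.70	28.88	20.83	46.15	22.42
4	11:01	08:01	15:02	12:02	03:01	11.27	4.57	5.95	8.08	10.11	11.19	22.25	17.22
5	33:03	03:02	58:01	13:02	06:09	10.62	8.91	6.74	7.90	14.26	10.76	9.81	8.72
6	02:07	01:02	46:01	08:03	06:01	9.25	6.41	6.80	8.59	9.16	11.48	6.89	13.21
7	33:03	14:03	44:03	13:02	06:04	7.39	11.82	7.38	5.82	9.52	7.04	2.29	4.45
8	01:01	06:02	37:01	10:01	05:01	6.60	7.25	8.53	10.10	5.62	6.58	3.56	5.27
9	11:01	03:04	13:01	15:01	06:01	6.38	1.93	3.36	3.71	5.63	7.78	12.75	8.74
10	02:01	03:04	13:01	12:02	03:01	5.79	10.75	9.15	6.73	5.75	4.26	2.44	2.37
11	11:01	01:02	46:01	09:01	03:03	5.76	2.37	3.06	3.55	5.64	7.69	9.97	7.48
12	11:01	04:01	15:01	04:06	03:02	5.58	4.31	4.54	4.14	5.97	6.81	4.46	6.65
13	33:03	07:06	44:03	07:01	02:02	4.65	5.46	4.72	3.78	4.49	4.07	2.79	6.54
14	01:01	06:02	57:01	07:01	03:03	4.50	6.64	6.20	5.27	4.56	3.61	1.42	3.20
15	11:01	08:01	15:02	15:01	06:01	4.40	1.32	2.24	2.03	3.06	5.86	10.12	6.30
16	24:02	01:02	54:01	04:05	04:01	4.38	4.90	4.60	4.76	4.67	3.57	2.59	4.86
17	11:01	07:02	40:01	08:03	06:01	4.21	2.24	2.44	2.30	4.85	6.14	4.18	5.03
18	02:07	01:02	46:01	14:54	05:02	3.80	0.78	1.26	3.00	1.97	3.51	7.49	10.14
19	11:01	03:04	13:01	12:02	03:01	3.67	3.75	3.76	3.61	3.37	3.84	4.34	3.63
20	02:03	07:02	38:02	16:02	05:02	3.64	1.15	1.73	1.35	3.22	3.78	10.11	3.45
21	11:01	07:02	40:01	09:01	03:03	3.59	1.83	1.95	2.01	4.58	4.95	4.01	3.63
22	02:01	03:03	15:11	09:01	03:03	3.55	4.75	4.21	4.25	4.02	3.25	1.45	2.22
23	32:01	12:02	52:01	15:02	06:01	3.18	3.82	3.83	4.40	3.31	3.07	1.06	1.65
24	24:02	01:02	46:01	09:01	03:03	3.14	1.62	1.99	2.66	3.32	3.61	4.52	3.98
25	11:01	14:02	51:01	09:01	03:03	3.14	3.70	2.44	3.60	3.38	3.38	2.40	3.31
26	24:02	14:02	51:01	09:01	03:03	3.13	2.62	3.57	3.22	3.48	3.20	2.25	2.66
27	11:01	07:02	07:02	01:01	05:01	2.89	1.83	2.46	4.92	1.83	2.63	1.08	6.62
28	03:01	07:02	07:02	15:01	06:02	2.84	4.45	5.20	3.13	2.49	2.32	0.93	1.04
30	11:01	12:02	52:01	15:02	06:01	2.57	4.09	3.96	4.70	2.14	2.46	1.11	1.19
31	11:01	03:04	13:01	16:02	05:02	2.45	0.59	0.83	1.23	1.91	2.17	7.71	2.88
32	03:01	05:01	44:02	13:01	06:03	2.43	3.75	3.29	3.16	1.60	1.83	0.64	3.78
37	32:01	04:01	44:03	07:01	02:02	2.23	2.48	3.70	2.92	1.77	2.95	0.51	0.90
38	02:07	01:02	46:01	12:02	03:01	2.11	1.24	1.36	1.16	1.90	1.96	3.00	4.23
42	11:01	03:02	58:01	03:01	02:01	1.83	0.72	1.16	0.97	2.05	1.98	3.77	1.54
52	29:01	15:05	07:05	10:01	05:01	1.65	0.78	0.88	1.34	1.13	1.19	4.27	2.32
68	24:02	04:03	15:25	12:02	03:01	1.35	0.39	0.34	0.47	0.36	0.20	0.72	7.90
79	02:03	07:02	52:01	14:04	05:03	1.26	1.26	0.71	0.30	0.85	0.45	0.29	5.11
81	24:02	03:04	13:01	15:01	06:01	1.25	0.45	0.48	0.37	0.91	1.42	3.91	1.62
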