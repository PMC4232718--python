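# 31 amino-acid physicochemical property scales used for binning
# nonsynonymous-change magnitudes into 8 categories.
# Curated approximate re-tabulation from standard amino-acid index
# compilations (Grantham polarity/volume/composition, Kyte-Doolittle
# hydropathy, Zimmerman bulkiness, Chou-Fasman secondary-structure
# propensities, Eisenberg consensus hydrophobicity, Woese polar
# requirement, and related scales). Values are adequate for ranking
# change magnitudes; they are not a verbatim copy of any single index.
property	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
tendency to form alpha-helix	1.42	0.98	0.67	1.01	0.7	1.11	1.51	0.57	1	1.08	1.21	1.16	1.45	1.13	0.57	0.77	0.83	1.08	0.69	1.06
average number of surrounding residues	6.05	5.7	5.04	4.95	7.86	5.45	5.1	6.16	5.8	7.51	7.37	4.88	6.39	6.62	5.65	5.53	5.81	6.98	6.73	7.62
beta-structure tendencies	0.83	0.93	0.89	0.54	1.19	1.1	0.37	0.75	0.87	1.6	1.3	0.74	1.05	1.38	0.55	0.75	1.19	1.37	1.47	1.7
bulkiness	11.5	14.28	12.82	11.68	13.46	14.45	13.57	3.4	13.69	21.4	21.4	15.71	16.25	19.8	17.43	9.47	15.77	21.67	18.03	21.57
buriedness	0.38	0.01	0.12	0.15	0.5	0.07	0.18	0.36	0.17	0.6	0.45	0.03	0.4	0.5	0.18	0.22	0.23	0.27	0.15	0.54
chromatographic index	9.9	4.6	5.4	2.8	2.8	9	3.2	5.6	8.2	17.1	17.6	3.5	14.9	18.8	14.8	6.9	9.5	17.1	15	14.3
coil tendencies	0.71	1.06	1.37	1.21	1.19	0.87	0.84	1.52	0.95	0.66	0.69	0.99	0.67	0.71	1.61	1.34	1.08	0.76	1.07	0.61
composition	0	0.65	1.33	1.38	2.75	0.89	0.92	0.74	0.58	0	0	0.33	0	0	0.39	1.42	0.71	0.13	0.2	0
compressibility	-25.5	-26.7	-24.2	-23.2	-32.8	-26.2	-24.7	-27	-31.5	-31.8	-31.7	-26.4	-31.5	-34.5	-23.4	-24.1	-25.4	-38.5	-35.5	-30.7
equilibrium constant (ionization of COOH)	2.34	2.17	2.02	1.88	1.96	2.17	2.19	2.34	1.82	2.36	2.36	2.18	2.28	1.83	1.99	2.21	2.09	2.38	2.2	2.32
helical contact area	26	68	43	40	44	56	50	0	59	64	60	59	63	73	38	29	42	88	76	53
hydropathy	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
isoelectric point	6	10.76	5.41	2.77	5.07	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.3	5.68	5.6	5.89	5.66	5.96
long-range non-bonded energy	-4.5	-5.4	-5.1	-4.9	-7.1	-5.4	-5	-4.6	-6	-7	-6.9	-4.9	-6.8	-7.2	-5	-4.8	-5.2	-7.5	-6.9	-6.7
mean r.m.s. fluctuation displacement	1.04	1.1	1.12	1.13	0.95	1.11	1.15	1.12	1.06	0.98	1	1.15	1	0.97	1.1	1.09	1.05	0.97	1	0.97
molecular volume	31	124	56	54	55	85	83	3	96	111	111	119	105	132	32.5	32	61	170	136	84
molecular weight	89.09	174.2	132.12	133.1	121.16	146.15	147.13	75.07	155.16	131.17	131.17	146.19	149.21	165.19	115.13	105.09	119.12	204.23	181.19	117.15
normalized consensus hydrophobicity	0.62	-2.53	-0.78	-0.9	0.29	-0.85	-0.74	0.48	-0.4	1.38	1.06	-1.5	0.64	1.19	0.12	-0.18	-0.05	0.81	0.26	1.08
partial specific volume	0.748	0.666	0.619	0.579	0.631	0.674	0.643	0.632	0.67	0.884	0.884	0.789	0.745	0.774	0.758	0.613	0.689	0.734	0.712	0.847
polar requirement	7	9.1	10	13	4.8	8.6	12.5	7.9	8.4	4.9	4.9	10.1	5.3	5	6.6	7.5	6.6	5.2	5.4	5.6
polarity	8.1	10.5	11.6	13	5.5	10.5	12.3	9	10.4	5.2	4.9	11.3	5.7	5.2	8	9.2	8.6	5.4	6.2	5.9
power to be at the C-terminal	0.96	0.88	1.14	1.07	1.19	1.2	1	0.99	1.03	0.93	1.01	1.08	0.99	1	1	1.06	1.05	1.02	1.07	0.97
power to be at the middle of alpha-helix	1.29	0.83	0.77	1	0.79	1.1	1.54	0.57	1.24	1.05	1.3	1.21	1.18	1.07	0.53	0.78	0.87	1.07	0.72	0.91
power to be at the N-terminal	1.05	0.78	1.1	1.6	0.72	1.11	1.55	0.82	0.94	0.86	0.96	0.83	0.95	0.94	1.69	1.05	1.07	0.91	0.82	0.84
refractive index	4.34	26.66	13.28	12	35.77	17.56	17.26	0	21.81	19.06	18.78	21.29	21.64	29.4	10.93	6.35	11.01	42.53	31.53	13.92
short and medium range non-bonded energy	-3.9	-4.1	-3.8	-3.7	-5.3	-4	-3.8	-3.6	-4.7	-5.5	-5.3	-3.9	-5.1	-5.6	-4.2	-3.7	-4	-5.9	-5.3	-5.2
solvent accessible reduction ratio	0.74	0.64	0.63	0.62	0.91	0.62	0.62	0.72	0.78	0.88	0.85	0.52	0.85	0.88	0.64	0.66	0.7	0.85	0.76	0.86
surrounding hydrophobicity	12.97	11.72	11.42	10.85	14.63	11.76	11.89	12.43	12.16	15.67	14.9	11.36	14.39	14	11.37	11.23	11.69	13.93	13.42	15.71
thermodynamic transfer hydrophobicity	0.5	0	0	0	0	0	0	0	0.5	1.8	1.8	0	1.3	2.5	1.4	-0.3	0.4	3.4	2.3	1.5
total non-bonded energy	-8.4	-9.5	-8.9	-8.6	-12.4	-9.4	-8.8	-8.2	-10.7	-12.5	-12.2	-8.8	-11.9	-12.8	-9.2	-8.5	-9.2	-13.4	-12.2	-11.9
turn tendencies	0.66	0.95	1.56	1.46	1.19	0.98	0.74	1.56	0.95	0.47	0.59	1.01	0.6	0.6	1.52	1.43	0.96	0.96	1.14	0.5
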