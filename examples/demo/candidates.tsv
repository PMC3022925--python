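gene_id	position	ref	alt	d	D	w	Q	n	ambiguous
G0001	70	C	A	80	165	0.051	83.6	78.3	false
G0001	144	C	T	69	72	0.306	76.6	71.4	false
G0001	45	C	T	79	240	1.078	54.5	48.3	false
G0001	145	A	T	28	59	1.359	58.7	61	false
G0002	140	A	T	50	175	0.937	52.5	76.5	true
G0002	241	G	C	23	227	0.715	78.8	49.2	false
G0002	243	T	C	1	200	0.057	96.8	71.4	false
G0002	120	C	T	28	212	0.267	69.9	70.3	false
G0002	174	T	G	37	213	1.079	71.7	80.5	false
G0002	168	G	C	91	153	0.35	54.8	94.5	false
G0002	48	G	A	9	35	0.711	83	41.2	false
G0003	248	G	C	0	132	1.446	80.1	65.4	false
G0003	86	T	A	18	233	0.005	76.5	84.2	false
G0003	144	A	T	32	152	0.086	87.9	80.7	false
G0003	102	T	A	45	154	0.359	59	84.6	false
G0003	279	T	G	77	179	0.606	71.6	42	false
G0003	183	A	G	41	160	1.419	73	74.3	false
G0004	149	C	G	17	61	0.547	73.1	64.2	false
G0004	78	T	G	70	197	0.886	29.8	88.6	false
G0004	96	A	T	90	196	0.916	93.2	53.7	false
G0004	87	G	T	91	118	1.295	85.4	59.6	false
G0004	30	A	T	84	121	0.829	96.9	88.6	false
G0005	24	A	T	95	182	0.704	68.7	81.2	false
G0005	45	G	T	58	244	0.536	63.3	54.9	false
G0005	81	A	G	37	167	1.206	70.6	78.8	false
G0005	39	T	G	45	168	0.751	71.9	48.6	false
G0005	156	T	C	71	454	0.443	93.2	63.8	false
G0005	210	A	G	32	129	1.337	90.2	49	false
G0005	174	A	C	61	200	0.732	73.4	76.1	false
G0006	57	C	G	87	94	0.231	61.4	83.2	false
G0006	146	T	C	82	190	0.339	45.2	48.9	false
G0006	189	T	C	41	113	1.04	59.1	42.3	false
G0007	93	C	A	78	239	1.327	78	80.9	false
G0007	129	C	A	98	225	1.221	53.9	62.3	false
G0007	141	A	G	93	152	1.096	78.7	84.8	false
G0007	87	T	A	41	140	1.393	21.7	88.9	false
G0008	123	G	A	4	197	0.887	74.3	43.7	false
G0008	15	C	T	47	246	0.324	98.9	76.1	false
G0008	18	T	A	21	248	0.264	78.2	48.8	false
G0008	201	C	T	72	245	0.139	77.2	50.7	false
G0008	45	A	G	37	246	0.817	53.9	85.5	false
G0008	190	A	C	90	164	1.249	88.4	90.3	false
G0008	6	G	A	35	164	0.483	79.6	73.7	false
G0009	205	T	G	67	155	0.484	80.6	56.1	false
G0009	168	G	T	100	240	0.17	54.7	77.7	false
G0009	183	A	G	34	178	0.741	70.9	68.8	false
G0010	90	C	A	24	52	0.316	88.4	97.5	false
G0010	93	C	A	99	159	1.137	93.7	72.7	false
G0010	156	T	C	95	175	1.237	34	53.9	false
G0010	150	C	T	93	243	0.88	90.5	68.4	false
G0010	142	G	A	96	120	0.868	67.9	49.8	false
G0010	102	A	C	41	56	0.754	55.7	42.6	false
G0010	189	C	T	3	228	0.105	92.1	47.1	false
G0011	141	A	G	78	178	0.964	82.1	86.1	false
G0011	24	A	C	89	192	1.269	52.7	55.2	false
G0011	73	T	G	9	96	0.983	71.3	96.8	false
G0011	162	A	C	89	121	0.929	80.7	93.7	false
G0011	138	C	G	60	127	1.379	81.7	45.6	false
G0011	231	T	C	21	231	0.365	59.5	43.7	false
G0011	324	G	T	66	162	1.267	74.8	79.1	false
G0012	45	G	A	55	121	1.26	94.3	76.2	false
G0012	243	G	C	97	218	0.348	80.6	41.2	false
G0012	175	C	T	47	73	0.938	96	86.1	false
G0012	249	C	T	24	185	1.291	99	48.1	false
G0013	169	T	G	50	84	1.476	98.6	98.2	false
G0013	141	G	T	78	91	1.105	64.6	23.3	false
G0013	81	C	T	96	108	1.137	65.5	92.6	false
G0014	137	C	A	73	251	0.665	91.9	97.6	false
G0014	133	A	C	8	112	0.543	64.4	49.9	false
G0014	99	G	C	93	198	1.475	72.5	55.4	false
G0014	261	A	G	45	160	0.055	89.2	59.7	false
G0014	24	C	A	62	218	1.44	53.6	68.5	false
G0014	237	C	T	21	217	0.188	76.5	54.3	false
G0014	138	A	C	44	47	0.99	79.8	81.4	false
G0015	285	G	C	100	216	0.65	77.7	75.3	false
G0015	52	C	A	44	90	0.399	64.3	50.8	false
G0015	192	C	A	23	234	0.142	53.8	53	false
G0015	270	T	A	16	205	1.153	68.4	65.3	false
G0015	92	T	C	47	64	0.135	78.6	2.5	false
G0015	15	T	C	40	207	1.187	23.6	60.6	false
G0016	267	T	C	10	58	0.415	69	42.4	false
G0016	315	T	C	87	209	0.384	77.1	48.7	false
G0017	196	T	G	83	219	2.838	85.1	65.6	false
G0017	96	G	T	0	226	0.872	79.3	43.8	false
G0017	90	T	C	63	206	0.662	60.6	84.4	false
G0017	99	A	G	84	143	0.66	69.6	56.9	false
G0017	36	T	A	91	146	0.126	51.4	45.5	false
G0018	165	A	C	23	203	0.838	90	60.4	false
G0018	138	T	G	67	184	0.992	68.9	45.6	false
G0018	122	T	A	99	121	1.004	37.5	70.7	false
G0019	193	T	A	54	246	1.076	53.9	71.1	false
G0019	102	T	C	47	153	0.729	87.4	92.8	false
G0019	23	T	C	93	134	0.289	63.5	77	false
G0019	135	A	T	10	131	0.093	88.7	62.2	false
G0019	169	A	C	35	89	1.342	69.7	71.5	false
G0019	273	T	A	78	244	1.18	62.6	47.4	false
G0019	309	G	A	43	213	1.382	89.7	94.7	false
G0019	81	A	G	10	156	0.832	94	75.9	false
G0019	300	C	T	49	189	0.118	84.5	90.3	false
G0020	36	T	G	80	193	0.045	57.8	73	false
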