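gene_id	position	ref	alt	effect_class	passes_filter
G0001	70	C	A	nonsynonymous_missense	true
G0001	144	C	T	silent	true
G0001	45	C	T	silent	true
G0001	145	A	T	nonsynonymous_missense	true
G0002	140	A	T	nonsynonymous_missense	false
G0002	241	G	C	nonsynonymous_missense	true
G0002	243	T	C	silent	false
G0002	120	C	T	silent	true
G0002	174	T	G	silent	true
G0002	168	G	C	silent	true
G0002	48	G	A	silent	true
G0003	248	G	C	nonsynonymous_missense	false
G0003	86	T	A	nonsynonymous_missense	true
G0003	144	A	T	silent	true
G0003	102	T	A	silent	true
G0003	279	T	G	silent	true
G0003	183	A	G	silent	true
G0004	149	C	G	nonsynonymous_missense	true
G0004	78	T	G	silent	false
G0004	96	A	T	silent	true
G0004	87	G	T	silent	true
G0004	30	A	T	silent	true
G0005	24	A	T	silent	true
G0005	45	G	T	silent	true
G0005	81	A	G	silent	true
G0005	39	T	G	silent	true
G0005	156	T	C	silent	false
G0005	210	A	G	silent	true
G0005	174	A	C	silent	true
G0006	57	C	G	silent	true
G0006	146	T	C	nonsynonymous_missense	false
G0006	189	T	C	silent	true
G0007	93	C	A	silent	true
G0007	129	C	A	nonsynonymous_nonsense	true
G0007	141	A	G	silent	true
G0007	87	T	A	silent	false
G0008	123	G	A	silent	false
G0008	15	C	T	silent	true
G0008	18	T	A	silent	true
G0008	201	C	T	silent	true
G0008	45	A	G	silent	true
G0008	190	A	C	nonsynonymous_missense	true
G0008	6	G	A	silent	true
G0009	205	T	G	nonsynonymous_missense	true
G0009	168	G	T	silent	true
G0009	183	A	G	silent	true
G0010	90	C	A	silent	true
G0010	93	C	A	silent	true
G0010	156	T	C	silent	false
G0010	150	C	T	silent	true
G0010	142	G	A	nonsynonymous_missense	true
G0010	102	A	C	silent	true
G0010	189	C	T	silent	false
G0011	141	A	G	silent	true
G0011	24	A	C	silent	true
G0011	73	T	G	nonsynonymous_missense	true
G0011	162	A	C	silent	true
G0011	138	C	G	silent	true
G0011	231	T	C	silent	true
G0011	324	G	T	silent	true
G0012	45	G	A	silent	true
G0012	243	G	C	nonsynonymous_missense	true
G0012	175	C	T	silent	true
G0012	249	C	T	silent	true
G0013	169	T	G	nonsynonymous_missense	true
G0013	141	G	T	silent	false
G0013	81	C	T	silent	true
G0014	137	C	A	nonsynonymous_nonsense	true
G0014	133	A	C	nonsynonymous_missense	true
G0014	99	G	C	silent	true
G0014	261	A	G	silent	true
G0014	24	C	A	silent	true
G0014	237	C	T	silent	true
G0014	138	A	C	silent	true
G0015	285	G	C	silent	true
G0015	52	C	A	silent	true
G0015	192	C	A	silent	true
G0015	270	T	A	silent	true
G0015	92	T	C	nonsynonymous_missense	false
G0015	15	T	C	silent	false
G0016	267	T	C	silent	true
G0016	315	T	C	silent	true
G0017	196	T	G	nonsynonymous_missense	false
G0017	96	G	T	silent	false
G0017	90	T	C	silent	true
G0017	99	A	G	silent	true
G0017	36	T	A	silent	true
G0018	165	A	C	silent	true
G0018	138	T	G	silent	true
G0018	122	T	A	nonsynonymous_missense	false
G0019	193	T	A	nonsynonymous_missense	true
G0019	102	T	C	silent	true
G0019	23	T	C	nonsynonymous_missense	true
G0019	135	A	T	silent	true
G0019	169	A	C	nonsynonymous_missense	true
G0019	273	T	A	silent	true
G0019	309	G	A	silent	true
G0019	81	A	G	silent	true
G0019	300	C	T	silent	true
G0020	36	T	G	silent	true
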