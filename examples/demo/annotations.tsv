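G0002	T001	synthetic pathway 1
G0009	T001	synthetic pathway 1
G0010	T001	synthetic pathway 1
G0012	T001	synthetic pathway 1
G0013	T001	synthetic pathway 1
G0017	T001	synthetic pathway 1
G0018	T001	synthetic pathway 1
G0003	T002	synthetic pathway 2
G0006	T002	synthetic pathway 2
G0009	T002	synthetic pathway 2
G0015	T002	synthetic pathway 2
G0020	T002	synthetic pathway 2
G0004	T003	synthetic pathway 3
G0006	T003	synthetic pathway 3
G0012	T003	synthetic pathway 3
G0016	T003	synthetic pathway 3
G0001	T004	synthetic pathway 4
G0002	T004	synthetic pathway 4
G0006	T004	synthetic pathway 4
G0007	T004	synthetic pathway 4
G0011	T004	synthetic pathway 4
G0017	T004	synthetic pathway 4
G0020	T004	synthetic pathway 4
G0005	T005	synthetic pathway 5
G0009	T005	synthetic pathway 5
G0015	T005	synthetic pathway 5
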