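sample_id	line	mi_counts	m_count	printed_x	printed_y
08H275	Spain	–	106	53	0
08H281	Spain	–	106	53	0
07C470	Spain	53 (at MII)	–	53	0
07F568	Spain	53	–	53	0
L1	Spain	53	ca106	53	0
L2	Spain	–	ca106–108	ca53–54	0
L3	Sweden	–	57	unknown	unknown
L4	Sweden	–	58	unknown	unknown
12M060	Sweden	28	57	27	1
12M058	Sweden	28	57	27	1
12M049	Sweden	29	–	29	0
12Z085	Sweden	29	58	29	0
10-B467	Sweden	29	ca58	29	0
13Y025	F1	–	82	unknown	unknown
13Y037	F1	–	82	unknown	unknown
13Y050	F1	–	82	unknown	unknown
13Y039	F1	–	82		
13Y058	F1	28	ca81	3	25
12Z065	F1	29 + 2s	ca82	5	24
13Y045	F1	29	ca82	5	24
13Y057	F1	29	–	unknown	unknown
13Y063	F1	29	ca82	5	24
12Z066	F1	29; 29 + s; 29 + 2s; 29 + 3s	ca82	5	24
12Z051	F1	29 + s; 29 + 2s	ca82	5	25
12Z054	F1	ca29 + s; ca29 + 2s; ca29 + 3s	–	unknown	unknown
L7	F2	–	ca73	unknown	unknown
L8	F2	–	ca77	unknown	unknown
L9	F2	–	ca77	unknown	unknown
L10	F2	–	ca82	unknown	unknown
L11	F2	–	ca82	unknown	unknown
L12	F2	–	83	unknown	unknown
L13	F2	–	83	unknown	unknown
L14	F2	–	83	unknown	unknown
L15	F2	–	85	unknown	unknown
L16	F2	–	ca90	unknown	unknown
13Y080	F2	31	ca82	11	20
11H440	F2	32	82	14	18
13Y079	F2	32	ca77	19	13
13Y082	F2	32	ca81	15	17
11H437	F2	32	–	unknown	unknown
13Y084	F2	32; 32 + s	82	14	18
13Y083	F2	34	ca83	19	15
11H479	F2	35	ca87	18	17
13Y077	F2	35; 35 + s	ca82	23	12
11H467	F2	35	ca83	22	13
13Y081	F2	36	ca85	23	13
11H439	F2	36	–	unknown	unknown
L20	F3	–	76	unknown	unknown
L21	F3	–	76	unknown	unknown
L22	F3	–	77	unknown	unknown
L23	F3	–	86	unknown	unknown
14A002	F3	29	ca75	12	17
14A004	F3	29	ca74	13	16
14A003	F3	31	ca77	16	15
14A001	F3	32	ca76	20	12
14A000	F3	33	ca82	17	16
14A005	F3	35	ca84	21	14
14B000	F4	32; 32 + s	ca79	17	15
14B003	F4	33	ca78	21	12
14B004	F4	33	ca82	17	16
14B002	F4	34	ca83	19	15
14B005	F4	37	ca86	25	12
14B001	F4	38	ca89	25	13
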