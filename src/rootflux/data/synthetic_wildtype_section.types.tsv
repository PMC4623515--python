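1	protoxylem
2	metaxylem
3	metaxylem
4	metaxylem
5	protoxylem
6	phloem
7	phloem
8	phloem-pole-procambium
9	phloem-pole-procambium
10	phloem-pole-procambium
11	phloem-pole-procambium
12	procambium
13	procambium
14	procambium
15	procambium
16	procambium
17	procambium
18	procambium
19	procambium
20	procambium
21	procambium
22	pericycle
23	pericycle
24	pericycle
25	pericycle
26	pericycle
27	pericycle
28	pericycle
29	pericycle
30	pericycle
31	pericycle
32	pericycle
33	pericycle
34	endodermis
35	endodermis
36	endodermis
37	endodermis
38	endodermis
39	endodermis
40	endodermis
41	endodermis
42	cortex
43	cortex
44	cortex
45	cortex
46	cortex
47	cortex
48	cortex
49	cortex
50	epidermis
51	epidermis
52	epidermis
53	epidermis
54	epidermis
55	epidermis
56	epidermis
57	epidermis
58	epidermis
59	epidermis
60	epidermis
61	epidermis
62	epidermis
63	epidermis
64	epidermis
65	epidermis
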