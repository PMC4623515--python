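1	protoxylem
2	protoxylem
3	protoxylem
4	protoxylem
5	protoxylem
6	protoxylem
7	protoxylem
8	protoxylem
9	protoxylem
10	pericycle
11	pericycle
12	pericycle
13	pericycle
14	pericycle
15	pericycle
16	pericycle
17	pericycle
18	pericycle
19	pericycle
20	endodermis
21	endodermis
22	endodermis
23	endodermis
24	endodermis
25	endodermis
26	endodermis
27	endodermis
28	cortex
29	cortex
30	cortex
31	cortex
32	cortex
33	cortex
34	cortex
35	cortex
36	epidermis
37	epidermis
38	epidermis
39	epidermis
40	epidermis
41	epidermis
42	epidermis
43	epidermis
44	epidermis
45	epidermis
46	epidermis
47	epidermis
48	epidermis
49	epidermis
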