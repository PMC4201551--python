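no	contig_clc	contig_suite	run_length	mapping_ambiguity
1	TT	TT	1	1
2	TTCCTATTTAATA	TTCCTATTTAATA	1	1
3	TAGAAATAAAAAATTCTAA	TAGAAATAAAAAATTCTAA	1	1
4	TAGAAATAAAAAATTCTAA	TAGAAATAAAAAATTCTAA	1	1
5	T	T	1	1
6	-	-	1	0
7	AA	AAA	10	0
8	C	C	3	0
9	T	T	3	0
10	G	G	3	0
11	C	C	3	0
12	C	C	3	0
13	G	G	3	0
14	G	G	3	0
15	C	C	3	0
16	C	C	3	0
17	G	G	3	0
18	C	C	3	0
19	G	G	3	0
20	C	C	3	0
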