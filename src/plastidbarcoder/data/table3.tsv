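no	position	type	ref_allele	allele_a	allele_b	most_probable
1	57036	MNV	TT	TT	AA	TT
2	65465	ins	-	-	TCCTATTTAATA	TTCCTATTTAATA
3	66897	MNV	CGAT	TAGA	CGAT	TAGAAATAAAAAATTCTAA
4	66902	SNP	C	A	C	TAGAAATAAAAAATTCTAA
5	17366	SNP	T	A	T	T
6	17368	SNP/del	C	A	-	-
7	3545	ins	-	AA	A	-
8	21808	del	C	C	-	C
9	57027	del	T	T	-	T
10	81342	del	G	G	-	G
11	91427	del	C	C	-	C
12	91589	del	C	C	-	C
13	97135	del	G	G	-	G
14	111639	del	G	G	-	G
15	116139	del	C	C	-	C
16	118025	del	C	C	-	C
17	119245	del	G	G	-	G
18	122914	del	C	C	-	C
19	123568	del	G	G	-	G
20	133816	del	C	C	-	C
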