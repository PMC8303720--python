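position	class	mutation	aa_change	n_samples
38	SHIFT	ggc/ggTGGTc	G13GG	1
40	SHIFT	acg/aATGGTGGTCATcg	T14NGGH *	1
41	MISS	aCg/aTg	T14M	4
42	SHIFT	gct/	A15 *	20
45	SHIFT	gtg/gGTCAACG	V16GQR *	4
48	SHIFT	ggc/CAggc	G17Q *	4
3421	SHIFT	gtc/gCATGtc	V210AC *	1
4077	MISS	Ctc/Ttc	L330F	2
4357	MISS	Ttt/Gtt	F398V	1
4540	MISS	gTg/gCg	V414A	9
6020	MISS	cAa/cGa	Q627R	1
6915	NON	Gaa/Taa	E700 *	1
7034	SHIFT	gat/gCGat	D740A *	18
7070	SHIFT	tgcatggtg/	CMV753	1
7120	MISS	gCt/gGt	A768G	3
9098	MISS	cAa/cCa	Q788P	1
9122	SHIFT	gga/GTAAgga	G793VR	8
9335	MISS	gCc/gTc	A822V	3
10491	SHIFT	gga/	G950	1
11708	MISS	cCg/cTg	P1079L	1
11726	MISS	gGa/gAa	G1085E	10
12507	MISS	Gaa/Aaa	E1195K	2
12748	MISS	aGt/aAt	S1209N	10
13285	MISS	Tcc/Acc	S1310T	1
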