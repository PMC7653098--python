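haplogroup	position	ref	alt
A	663	A	G
A	1736	A	G
A	4248	T	C
A	4824	A	G
A	8794	C	T
A	16290	C	T
A	16319	G	A
B	499	G	A
B	827	A	G
B	16189	T	C
B	16217	T	C
C	3552	T	A
C	8584	G	A
C	9545	A	G
C	13263	A	G
C	16327	C	T
D	4883	C	T
D	5178	C	A
D	8414	C	T
D	16362	T	C
H	3010	G	A
H	6776	T	C
H	12405	C	T
J	4216	T	C
J	10398	A	G
J	12612	A	G
J	13708	G	A
J	16069	C	T
L	2416	T	C
L	3594	C	T
L	8701	A	G
L	9540	T	C
L	10873	T	C
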