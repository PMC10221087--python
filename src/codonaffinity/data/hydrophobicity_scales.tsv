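scale	higher_is_hydrophobic	amino_acid	value
kyte_doolittle	True	A	1.8
kyte_doolittle	True	R	-4.5
kyte_doolittle	True	N	-3.5
kyte_doolittle	True	D	-3.5
kyte_doolittle	True	C	2.5
kyte_doolittle	True	Q	-3.5
kyte_doolittle	True	E	-3.5
kyte_doolittle	True	G	-0.4
kyte_doolittle	True	H	-3.2
kyte_doolittle	True	I	4.5
kyte_doolittle	True	L	3.8
kyte_doolittle	True	K	-3.9
kyte_doolittle	True	M	1.9
kyte_doolittle	True	F	2.8
kyte_doolittle	True	P	-1.6
kyte_doolittle	True	S	-0.8
kyte_doolittle	True	T	-0.7
kyte_doolittle	True	W	-0.9
kyte_doolittle	True	Y	-1.3
kyte_doolittle	True	V	4.2
hopp_woods	False	A	-0.5
hopp_woods	False	R	3.0
hopp_woods	False	N	0.2
hopp_woods	False	D	3.0
hopp_woods	False	C	-1.0
hopp_woods	False	Q	0.2
hopp_woods	False	E	3.0
hopp_woods	False	G	0.0
hopp_woods	False	H	-0.5
hopp_woods	False	I	-1.8
hopp_woods	False	L	-1.8
hopp_woods	False	K	3.0
hopp_woods	False	M	-1.3
hopp_woods	False	F	-2.5
hopp_woods	False	P	0.0
hopp_woods	False	S	0.3
hopp_woods	False	T	-0.4
hopp_woods	False	W	-3.4
hopp_woods	False	Y	-2.3
hopp_woods	False	V	-1.5
eisenberg	True	A	0.62
eisenberg	True	R	-2.53
eisenberg	True	N	-0.78
eisenberg	True	D	-0.9
eisenberg	True	C	0.29
eisenberg	True	Q	-0.85
eisenberg	True	E	-0.74
eisenberg	True	G	0.48
eisenberg	True	H	-0.4
eisenberg	True	I	1.38
eisenberg	True	L	1.06
eisenberg	True	K	-1.5
eisenberg	True	M	0.64
eisenberg	True	F	1.19
eisenberg	True	P	0.12
eisenberg	True	S	-0.18
eisenberg	True	T	-0.05
eisenberg	True	W	0.81
eisenberg	True	Y	0.26
eisenberg	True	V	1.08
janin	True	A	0.3
janin	True	R	-1.4
janin	True	N	-0.5
janin	True	D	-0.6
janin	True	C	0.9
janin	True	Q	-0.7
janin	True	E	-0.7
janin	True	G	0.3
janin	True	H	-0.1
janin	True	I	0.7
janin	True	L	0.5
janin	True	K	-1.8
janin	True	M	0.4
janin	True	F	0.5
janin	True	P	-0.3
janin	True	S	-0.1
janin	True	T	-0.2
janin	True	W	0.3
janin	True	Y	-0.4
janin	True	V	0.6
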