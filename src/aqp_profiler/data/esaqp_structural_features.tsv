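name	subfamily	aa	tm	mw_kda	pi	npa_lb	npa_le	h2	h5	le1	le2	p1	p2	p3	p4	p5
EsPIP1;1	PIP	286	6	30.77	9.14	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP1;2	PIP	286	6	30.60	9.16	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP1;3	PIP	286	6	30.62	9.02	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP1;4	PIP	286	6	30.56	9.02	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP1;5	PIP	287	6	30.61	9.00	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP2;1	PIP	287	6	30.48	6.95	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP2;2	PIP	284	6	30.21	6.50	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP2;3	PIP	285	6	30.31	6.51	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP2;4	PIP	285	6	30.12	7.62	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP2;5	PIP	286	6	30.57	8.82	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP2;6	PIP	290	6	31.11	7.69	NPA	NPA	F	H	T	R	Q	S	A	F	W
EsPIP2;7	PIP	281	6	29.82	9.11	NPA	NPA	F	H	T	R	M	S	A	F	W
EsTIP1;1	TIP	251	6	25.62	6.03	NPA	NPA	H	I	A	V	T	A	A	Y	W
EsTIP1;2	TIP	253	6	25.70	5.32	NPA	NPA	H	I	A	V	T	A	A	Y	W
EsTIP1;3	TIP	252	6	25.85	5.10	NPA	NPA	H	I	A	V	T	S	A	Y	W
EsTIP2;1	TIP	277	6	28.32	7.80	NPA	NPA	H	I	G	R	T	S	A	Y	W
EsTIP2;2	TIP	250	6	25.02	4.87	NPA	NPA	H	I	G	R	T	S	A	Y	W
EsTIP2;3	TIP	243	6	24.31	4.73	NPA	NPA	H	I	G	R	T	S	A	Y	W
EsTIP2;4	TIP	254	6	25.85	5.43	NPA	NPA	H	I	G	R	T	S	A	Y	W
EsTIP3;1	TIP	265	6	27.94	7.17	NPA	NPA	H	T	A	R	T	A	A	Y	W
EsTIP3;2	TIP	267	6	28.29	6.58	NPA	NPA	H	M	A	R	T	T	A	Y	W
EsTIP4;1	TIP	249	6	26.16	5.49	NPA	NPA	H	I	A	R	T	S	A	Y	W
EsTIP5;1	TIP	257	6	26.70	7.72	NPA	NPA	N	V	G	C	V	A	A	Y	W
EsNIP1;2	NIP	297	6	31.80	8.83	NPA	NPA	W	V	A	R	F	S	A	Y	L
EsNIP2;1	NIP	286	6	30.56	6.78	NPA	NPG	W	V	A	R	F	S	A	Y	L
EsNIP3;1	NIP	323	6	34.46	5.94	NPA	NPA	W	I	A	R	F	S	A	Y	L
EsNIP4;1	NIP	283	6	30.49	8.73	NPA	NPA	W	V	A	R	F	S	A	Y	L
EsNIP4;2	NIP	284	6	30.34	8.80	NPA	NPA	W	V	A	R	F	S	A	Y	L
EsNIP4;3	NIP	283	6	30.30	8.98	NPA	NPA	W	V	A	R	F	S	A	Y	L
EsNIP5;1	NIP	301	6	31.20	8.31	NPS	NPA	A	I	G	R	F	T	A	Y	L
EsNIP6;1	NIP	305	6	31.78	8.57	NPA	NPA	A	I	A	R	F	T	A	Y	L
EsNIP7;1	NIP	275	6	28.62	6.12	NPS	NPA	A	V	G	R	Y	S	A	Y	L
EsSIP1;1	SIP	238	6	25.41	9.89	NPT	NPA	I	V	P	I	I	A	A	Y	W
EsSIP1;2	SIP	242	6	25.96	9.83	NPC	NPA	V	F	P	I	I	A	A	Y	W
EsSIP2;1	SIP	237	6	25.85	9.64	NPL	NPA	S	H	G	A	F	V	A	Y	W
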