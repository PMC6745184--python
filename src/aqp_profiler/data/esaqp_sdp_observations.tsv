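protein	substrate	SDP1	SDP2	SDP3	SDP4	SDP5	SDP6	SDP7	SDP8	SDP9
EsTIP2;1	ammonia	T	L	T	V	A	S	H	P	A
EsTIP3;1	ammonia	T	L	G	T	A	S	H	P	A
EsNIP1;2	ammonia	F	K	F	T	G	D	L	E	T
EsNIP4;1	ammonia	F	T	F	T	A	D	L	E	T
EsNIP4;3	ammonia	F	T	F	T	A	D	L	E	T
EsPIP1;1	boric_acid	T	I	H	P	E	L	L	T	P
EsPIP1;2	boric_acid	T	I	H	P	E	L	L	T	P
EsPIP1;3	boric_acid	T	I	H	P	E	L	L	T	P
EsPIP1;4	boric_acid	T	I	H	P	E	L	L	T	P
EsPIP1;5	boric_acid	T	I	H	P	E	L	L	T	P
EsPIP2;5	boric_acid	T	I	H	P	E	L	L	T	P
EsNIP5;1	boric_acid	T	I	H	P	E	L	L	A	P
EsNIP6;1	boric_acid	T	I	H	P	E	L	L	A	P
EsNIP7;1	boric_acid	V	I	H	P	E	L	L	T	P
EsPIP1;1	co2	L	I	C	A	I	D	W	D	W
EsPIP1;2	co2	V	I	C	A	I	D	W	D	W
EsPIP1;3	co2	V	M	C	A	I	D	W	D	W
EsPIP1;4	co2	V	M	C	A	I	D	W	D	W
EsPIP1;5	co2	V	I	C	A	I	D	W	D	W
EsPIP2;4	co2	V	I	C	A	V	E	W	D	W
EsPIP1;1	h2o2	A	G	V	F	I	H	F	V	P
EsPIP1;2	h2o2	A	G	V	F	I	H	F	V	P
EsPIP1;3	h2o2	A	G	V	F	I	H	F	V	P
EsPIP1;4	h2o2	A	G	V	F	I	H	F	V	P
EsPIP1;5	h2o2	A	G	V	F	I	H	F	V	P
EsPIP2;1	h2o2	A	G	V	F	I	H	F	V	P
EsPIP2;2	h2o2	A	G	V	F	I	H	F	V	P
EsPIP2;3	h2o2	A	G	V	F	I	H	F	V	P
EsPIP2;4	h2o2	A	G	V	F	I	Q	F	V	P
EsPIP2;5	h2o2	A	G	V	F	I	H	F	V	P
EsPIP2;6	h2o2	A	G	V	F	I	Q	F	V	P
EsPIP2;7	h2o2	A	G	V	F	I	H	F	V	P
EsTIP1;1	h2o2	S	A	L	A	I	H	Y	A	P
EsTIP1;2	h2o2	S	A	L	A	I	H	Y	A	P
EsTIP1;3	h2o2	A	A	L	S	I	H	Y	V	P
EsTIP2;1	h2o2	S	A	L	V	I	H	Y	V	P
EsTIP2;2	h2o2	S	A	L	V	I	I	Y	V	P
EsTIP2;3	h2o2	S	A	L	V	I	I	Y	V	P
EsTIP3;2	h2o2	A	A	L	A	I	H	Y	V	P
EsTIP4;1	h2o2	S	A	L	L	T	H	Y	V	P
EsNIP1;2	h2o2	S	A	L	L	V	I	Y	V	P
EsNIP3;1	h2o2	S	A	L	V	I	L	Y	V	P
EsNIP5;1	h2o2	S	A	L	V	V	L	Y	V	P
EsPIP1;1	urea	H	P	F	F	L	P	G	G	N
EsPIP1;2	urea	H	P	F	F	L	P	G	G	N
EsPIP1;3	urea	H	P	F	F	L	P	G	G	N
EsPIP1;4	urea	H	P	F	F	L	P	G	G	N
EsPIP1;5	urea	H	P	F	F	L	P	G	G	N
EsPIP2;1	urea	H	P	F	F	L	P	G	G	N
EsPIP2;2	urea	H	P	F	F	L	P	G	G	N
EsPIP2;3	urea	H	P	F	F	L	P	G	G	N
EsPIP2;4	urea	H	P	F	F	L	P	G	G	N
EsPIP2;5	urea	H	P	F	F	L	P	G	G	N
EsPIP2;6	urea	H	P	F	F	L	P	G	G	N
EsPIP2;7	urea	H	P	F	F	L	P	G	G	N
EsTIP1;1	urea	H	P	F	F	L	A	G	S	N
EsTIP1;2	urea	H	P	F	F	L	A	G	S	N
EsTIP1;3	urea	H	P	F	F	L	A	G	S	N
EsTIP2;1	urea	H	P	F	A	L	P	G	S	N
EsTIP2;2	urea	H	P	L	A	L	P	G	S	N
EsTIP2;3	urea	H	P	L	A	L	P	G	S	N
EsTIP2;4	urea	H	P	F	V	L	P	G	S	N
EsTIP3;1	urea	H	P	F	L	L	P	G	S	N
EsTIP3;2	urea	H	P	L	L	L	P	G	S	N
EsTIP4;1	urea	H	P	I	L	L	A	G	S	N
EsTIP5;1	urea	H	P	F	A	L	P	G	S	N
EsNIP1;2	urea	H	P	I	A	L	P	G	S	N
EsNIP2;1	urea	H	P	I	A	L	E	G	S	N
EsNIP3;1	urea	H	P	I	A	L	P	G	S	N
EsNIP4;1	urea	H	P	V	A	L	P	G	S	N
EsNIP4;2	urea	H	P	F	A	L	P	G	S	N
EsNIP4;3	urea	H	P	I	A	L	P	G	S	N
EsNIP5;1	urea	H	P	I	A	L	P	G	S	N
EsNIP6;1	urea	H	P	I	A	L	P	S	S	N
EsNIP7;1	urea	H	P	I	A	V	P	G	S	N
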