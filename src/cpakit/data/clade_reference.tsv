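clade	family	s1	s2	s3	s4	s5	s6	s7	s8	aux	electrogenicity_annotation	selectivity_annotation	provenance	representatives
NhaP-I/NHE	CPA1	P	T	D	P	E	N	D	R	-	electroneutral	Na	text-derived	HsNHE1;EcNhaP
NHA	CPA1	A	T	D	V	E	N	D	R	-	electroneutral	Na	figure-derived	fungal NHA
NhaP-II K+-specific	CPA1	S	T	D	A	E	N	D	R	-	electroneutral	K	text-derived	NhaP2
NhaP-III	CPA1	A	S	D	P	E	N	D	R	-	unknown	unknown	figure-derived	-
archaeal-NhaP-II Na+-specific	CPA1	A	T	D	P	E	N	D	R	-	electroneutral	Na	text-derived	MjNhaP1;PaNhaP
bacterial-NhaP-II Na+-specific	CPA1	G	T	D	P	E	N	D	R	-	electroneutral	Na	figure-derived	-
NhaA	CPA2	A	T	D	I	L	D	D	K	P	electrogenic	Na	text-derived	EcNhaA
NapA-I	CPA2	A	T	D	V	L	D	D	K	-	electrogenic	Na	figure-derived	TtNapA
NapA-II	CPA2	G	T	D	I	L	D	D	K	-	electrogenic	unknown	figure-derived	-
GerN	CPA2	A	T	D	M	L	D	D	K	-	electrogenic	unknown	figure-derived	BsGerN
CHX-like	CPA2	A	S	S	T	S	N	D	K	-	unknown	K	figure-derived	AtCHX17
Kef-like	CPA2	L	S	S	T	A	Q	D	K	-	electroneutral	K	text-derived	AtKEA2;PaKefB
KhaB	CPA2	A	T	D	T	L	N	D	K	-	unknown	K	figure-derived	SsNhaS5
animal-NHA-like	CPA2	A	T	D	I	L	D	D	R	E	electroneutral	Na	figure-derived	HsNHA2
uncharacterized-prokaryotic	CPA2	A	T	D	I	L	N	D	K	-	unknown	unknown	figure-derived	-
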