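name	hcp_areas	hemisphere	x	y	z	audio_only
S2	OP1-4	left	-51	-17	15	0
pI	Ig,PoI1,PoI2	left	-39	-9	0	0
aI	AAIC,AVI,MI	left	-35	14	-4	0
Foper	FOP1-5	left	-40	9	6	0
S1	1,2,3a-b	left	-41	-26	51	0
SMA	SCEF,6ma,6mp	left	-11	-1	63	0
pACC	a24	left	-4	40	0	0
ACC	p24	left	-3	36	16	0
MCC	a24pr,p24pr,33pr	left	-3	10	34	0
dPCC	23d,d23ab	left	-3	-31	34	0
vPCC	v23ab	left	-4	-55	17	0
PPC	PGp,PGs,PGi,PFm,PFt,PFop,IP0-2	left	-49	-47	41	0
Prec	7m,31a,31pv,DVT,31pd	left	-7	-44	39	0
OFC	10d,10v,10pp	left	-7	57	-4	0
DLPFC	8c,9a,46,9-46v/d	left	-35	40	24	0
Amyg	amyg	left	-24	-6	-21	0
Hipp	EC,H,PeEc	left	-24	-18	-22	0
A1	A1,PBelt,MBelt,LBelt	left	-48	-21	5	1
S2	OP1-4	right	52	-15	15	0
pI	Ig,PoI1,PoI2	right	39	-9	1	0
aI	AAIC,AVI,MI	right	36	15	-4	0
Foper	FOP1-5	right	40	11	6	0
S1	1,2,3a-b	right	41	-25	51	0
SMA	SCEF,6ma,6mp	right	14	0	63	0
pACC	a24	right	3	39	0	0
ACC	p24	right	2	36	16	0
MCC	a24pr,p24pr,33pr	right	3	7	36	0
dPCC	23d,d23ab	right	1	-29	35	0
vPCC	v23ab	right	3	-53	18	0
PPC	PGp,PGs,PGi,PFm,PFt,PFop,IP0-2	right	50	-44	42	0
Prec	7m,31a,31pv,DVT,31pd	right	7	-46	39	0
OFC	10d,10v,10pp	right	6	54	-6	0
DLPFC	8c,9a,46,9-46v/d	right	34	42	24	0
Amyg	amyg	right	22	-3	-21	0
Hipp	EC,H,PeEc	right	24	-18	-21	0
A1	A1,PBelt,MBelt,LBelt	right	50	-19	7	1
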