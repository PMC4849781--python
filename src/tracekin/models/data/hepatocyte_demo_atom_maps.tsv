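reaction_id	substrate	sub_carbon	product	prod_carbon
aldo1	FBPa#1	1	DHAP#1	1
aldo1	FBPa#1	2	DHAP#1	2
aldo1	FBPa#1	3	DHAP#1	3
aldo1	FBPa#1	4	GAP#1	1
aldo1	FBPa#1	5	GAP#1	2
aldo1	FBPa#1	6	GAP#1	3
aldo2	Fru1P#1	1	DHAP#1	1
aldo2	Fru1P#1	2	DHAP#1	2
aldo2	Fru1P#1	3	DHAP#1	3
aldo2	Fru1P#1	4	Gra#1	1
aldo2	Fru1P#1	5	Gra#1	2
aldo2	Fru1P#1	6	Gra#1	3
aldo3	FBPa#1	1	Fru1P#1	1
aldo3	FBPa#1	2	Fru1P#1	2
aldo3	FBPa#1	3	Fru1P#1	3
aldo3	FBPa#1	4	GAP#1	1
aldo3	FBPa#1	5	GAP#1	2
aldo3	FBPa#1	6	GAP#1	3
aldo3	Gra#1	1	Fru1P#1	4
aldo3	Gra#1	2	Fru1P#1	5
aldo3	Gra#1	3	Fru1P#1	6
eno	PG2#1	1	PEP#1	1
eno	PG2#1	2	PEP#1	2
eno	PG2#1	3	PEP#1	3
fbasea	FBPa#1	1	F6Pa#1	1
fbasea	FBPa#1	2	F6Pa#1	2
fbasea	FBPa#1	3	F6Pa#1	3
fbasea	FBPa#1	4	F6Pa#1	4
fbasea	FBPa#1	5	F6Pa#1	5
fbasea	FBPa#1	6	F6Pa#1	6
fbaseb	FBPb#1	1	F6Pb#1	1
fbaseb	FBPb#1	2	F6Pb#1	2
fbaseb	FBPb#1	3	F6Pb#1	3
fbaseb	FBPb#1	4	F6Pb#1	4
fbaseb	FBPb#1	5	F6Pb#1	5
fbaseb	FBPb#1	6	F6Pb#1	6
fruhk	cFru#1	1	Fru1P#1	1
fruhk	cFru#1	2	Fru1P#1	2
fruhk	cFru#1	3	Fru1P#1	3
fruhk	cFru#1	4	Fru1P#1	4
fruhk	cFru#1	5	Fru1P#1	5
fruhk	cFru#1	6	Fru1P#1	6
frutr	eFru#1	1	cFru#1	1
frutr	eFru#1	2	cFru#1	2
frutr	eFru#1	3	cFru#1	3
frutr	eFru#1	4	cFru#1	4
frutr	eFru#1	5	cFru#1	5
frutr	eFru#1	6	cFru#1	6
g6pasea	G6Pa#1	1	cGlc#1	1
g6pasea	G6Pa#1	2	cGlc#1	2
g6pasea	G6Pa#1	3	cGlc#1	3
g6pasea	G6Pa#1	4	cGlc#1	4
g6pasea	G6Pa#1	5	cGlc#1	5
g6pasea	G6Pa#1	6	cGlc#1	6
g6paseb	G6Pb#1	1	cGlc#1	1
g6paseb	G6Pb#1	2	cGlc#1	2
g6paseb	G6Pb#1	3	cGlc#1	3
g6paseb	G6Pb#1	4	cGlc#1	4
g6paseb	G6Pb#1	5	cGlc#1	5
g6paseb	G6Pb#1	6	cGlc#1	6
gapdh	GAP#1	1	BPG#1	1
gapdh	GAP#1	2	BPG#1	2
gapdh	GAP#1	3	BPG#1	3
gka	cGlc#1	1	G6Pa#1	1
gka	cGlc#1	2	G6Pa#1	2
gka	cGlc#1	3	G6Pa#1	3
gka	cGlc#1	4	G6Pa#1	4
gka	cGlc#1	5	G6Pa#1	5
gka	cGlc#1	6	G6Pa#1	6
gkb	cGlc#1	1	G6Pb#1	1
gkb	cGlc#1	2	G6Pb#1	2
gkb	cGlc#1	3	G6Pb#1	3
gkb	cGlc#1	4	G6Pb#1	4
gkb	cGlc#1	5	G6Pb#1	5
gkb	cGlc#1	6	G6Pb#1	6
glctr	eGlc#1	1	cGlc#1	1
glctr	eGlc#1	2	cGlc#1	2
glctr	eGlc#1	3	cGlc#1	3
glctr	eGlc#1	4	cGlc#1	4
glctr	eGlc#1	5	cGlc#1	5
glctr	eGlc#1	6	cGlc#1	6
gp	Glyc#1	1	G1P#1	1
gp	Glyc#1	2	G1P#1	2
gp	Glyc#1	3	G1P#1	3
gp	Glyc#1	4	G1P#1	4
gp	Glyc#1	5	G1P#1	5
gp	Glyc#1	6	G1P#1	6
gpia	G6Pa#1	1	F6Pa#1	1
gpia	G6Pa#1	2	F6Pa#1	2
gpia	G6Pa#1	3	F6Pa#1	3
gpia	G6Pa#1	4	F6Pa#1	4
gpia	G6Pa#1	5	F6Pa#1	5
gpia	G6Pa#1	6	F6Pa#1	6
gpib	G6Pb#1	1	F6Pb#1	1
gpib	G6Pb#1	2	F6Pb#1	2
gpib	G6Pb#1	3	F6Pb#1	3
gpib	G6Pb#1	4	F6Pb#1	4
gpib	G6Pb#1	5	F6Pb#1	5
gpib	G6Pb#1	6	F6Pb#1	6
gs	UDPG#1	1	Glyc#1	1
gs	UDPG#1	2	Glyc#1	2
gs	UDPG#1	3	Glyc#1	3
gs	UDPG#1	4	Glyc#1	4
gs	UDPG#1	5	Glyc#1	5
gs	UDPG#1	6	Glyc#1	6
lactr	cLac#1	1	eLac#1	1
lactr	cLac#1	2	eLac#1	2
lactr	cLac#1	3	eLac#1	3
ldh	Pyr#1	1	cLac#1	1
ldh	Pyr#1	2	cLac#1	2
ldh	Pyr#1	3	cLac#1	3
pfkla	F6Pa#1	1	FBPa#1	1
pfkla	F6Pa#1	2	FBPa#1	2
pfkla	F6Pa#1	3	FBPa#1	3
pfkla	F6Pa#1	4	FBPa#1	4
pfkla	F6Pa#1	5	FBPa#1	5
pfkla	F6Pa#1	6	FBPa#1	6
pfklb	F6Pb#1	1	FBPb#1	1
pfklb	F6Pb#1	2	FBPb#1	2
pfklb	F6Pb#1	3	FBPb#1	3
pfklb	F6Pb#1	4	FBPb#1	4
pfklb	F6Pb#1	5	FBPb#1	5
pfklb	F6Pb#1	6	FBPb#1	6
pgk	BPG#1	1	PG3#1	1
pgk	BPG#1	2	PG3#1	2
pgk	BPG#1	3	PG3#1	3
pglm	G6Pb#1	1	G1P#1	1
pglm	G6Pb#1	2	G1P#1	2
pglm	G6Pb#1	3	G1P#1	3
pglm	G6Pb#1	4	G1P#1	4
pglm	G6Pb#1	5	G1P#1	5
pglm	G6Pb#1	6	G1P#1	6
pgm	PG3#1	1	PG2#1	1
pgm	PG3#1	2	PG2#1	2
pgm	PG3#1	3	PG2#1	3
pk	PEP#1	1	Pyr#1	1
pk	PEP#1	2	Pyr#1	2
pk	PEP#1	3	Pyr#1	3
tim	DHAP#1	1	GAP#1	3
tim	DHAP#1	2	GAP#1	2
tim	DHAP#1	3	GAP#1	1
trik	Gra#1	1	GAP#1	1
trik	Gra#1	2	GAP#1	2
trik	Gra#1	3	GAP#1	3
ugt	G1P#1	1	UDPG#1	1
ugt	G1P#1	2	UDPG#1	2
ugt	G1P#1	3	UDPG#1	3
ugt	G1P#1	4	UDPG#1	4
ugt	G1P#1	5	UDPG#1	5
ugt	G1P#1	6	UDPG#1	6
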