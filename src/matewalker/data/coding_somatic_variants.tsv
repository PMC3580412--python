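position	gene	codon_change	consequence	sift
Chr1:71831141G/A	NEGR1	503C>T	T168I	Damaging
Chr1:149227247C/T	ANXA9	760C>T	R245C	Damaging
Chr1:156702726C/A	OR10K1	751C>A	H251N	Damaging
Chr1:220801358G/T	TAF1A	1211C>A	A404D	Damaging
Chr1:226621463T/G	OBSCN	19592T>G	F6531C	Not scored
Chr1:238137913G/A	CHRM3	539G>A	R180Q	Damaging
Chr2:49235000G/A	FSHR	61C>T	R21W	Tolerated
Chr2:165735207G/C	SCN3A	362C>G	A121G	Damaging
Chr2:178905886C/T	OSBPL6	529C>T	R177X	-
Chr3:109658364C/T	MYH15	2137G>A	G713R	Damaging
Chr3:129258301T/G	SEC61A1	280T>G	L94V	Damaging
Chr4:6670038G/A	MAN2B2	2732G>A	R911H	Tolerated
Chr6:28336272A/G	NKAPL	1144A>G	S382G	Damaging
Chr7:2599270C/T	IQCE	1333C>T	R445X	-
Chr7:43813258G/A	BLVRA	790G>A	G264S	Tolerated
Chr8:76091857G/T	CRISPLD1	950G>T	C317F	Damaging
Chr9:33301117G/A	NFX1	1240G>A	G414R	Damaging
Chr10:17777173T/C	STAM	364T>C	Y122H	Damaging
Chr10:99328071C/T	ANKRD2	274C>T	R92W	Damaging
Chr11:6368506-6368518del	SMPD1	102-114del	L35WfsX72	-
Chr11:92170718A/T	FAT3	4894A>T	M1632L	Not scored
Chr11:116661033A/T	RNF214	2068A>T	T690S	Not scored
Chr12:1854754C/T	CACNA2D4	1730G>A	G577E	Damaging
Chr12:5902149C/A	ANO2	93G>T	Q31H	Damaging
Chr12:25289551C/A	KRAS	35G>T	G12V	Damaging
Chr14:19598288-19598307del	OR4L1	245-264del	I82TfsX104	-
Chr15:32142462G/A	CHRM5	252G>A	M84I	Damaging
Chr15:83002258G/C	NMB	130C>G	H44D	Tolerated
Chr17:11543819G/A	DNAH9	4919G>A	R1640Q	Tolerated
Chr17:41416912C/G	MAPT	905C>G	T302R	Damaging
Chr18:42815392C/T	TCEB3B	242G>A	R81Q	Tolerated
Chr18:46845916C/T	SMAD4	1081C>T	R361C	Damaging
Chr20:25405049-25405055del	NINL	2872-2878del	W958HfsX960	-
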